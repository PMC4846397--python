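"""End-to-end orchestration: simulate or ingest, analyze, report.

A single :class:`RunConfig` drives the whole analysis so that a run is
reproducible from one structured file plus one seed: per-allele PSM
filtering and collapse, range classification, pairwise allelic
comparison, domain partition and UCD detection, domain-pair matrices,
envelope geometry, and CD summaries. All numeric outputs land in a
machine-readable JSON summary (byte-identical under a fixed seed and
config) and every table is also emitted as CSV; figures are optional
and their failure degrades to text output with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from httxl import __version__
from httxl.cd import helicity_trend, melt_summary, mre_at
from httxl.classify import RangeThresholds, categorize_set, classification_table
from httxl.compare import ContactSet, domain_pair_summary, pairwise_matrix
from httxl.domains import (
    build_partition,
    coverage_profile,
    detect_uncrosslinked_region,
)
from httxl.geometry import geometry_report
from httxl.simulate import (
    SimulationParams,
    build_solenoid_bead_model,
    perturb_allele,
    simulate_cd,
    simulate_crosslinks,
    simulate_melt,
)
from httxl.xlink_io import (
    FilterCriteria,
    apply_identification_filters,
    collapse_to_site_pairs,
    read_psm_table,
    write_psm_table,
)

logger = logging.getLogger("httxl")

__all__ = ["RunConfig", "run_pipeline", "render_report", "load_config"]


@dataclass
class RunConfig:
    """Everything one end-to-end run depends on.

    Exactly one crosslink data source must be configured: either
    ``psm_tables`` (paths to real xQuest-style exports, one per allele)
    or the simulation block (``simulate_xl`` true).
    """

    out_dir: str = "httxl_out"
    seed: int = 0
    alleles: tuple[tuple[str, int], ...] = (("Q23", 23), ("Q46", 46), ("Q78", 78))
    simulate_xl: bool = True
    psm_tables: Mapping[str, str] | None = None
    sim_params: SimulationParams = field(default_factory=SimulationParams)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    thresholds: RangeThresholds = field(default_factory=RangeThresholds)
    chain_length: int = 3144
    minor_site: int = 500
    hinge_interval: tuple[int, int] = (1184, 1254)
    ucd_interval: tuple[int, int] = (1800, 2300)
    detect_ucd: bool = True
    profile_window: int = 25
    profile_categories: tuple[str, ...] = ("short", "mid")
    # Envelope geometry block (measured volume takes precedence).
    geometry_shape: str = "sphere"
    geometry_dimensions: tuple[float, ...] = (115.0,)
    geometry_outer_volume: float | None = 861829.0
    molecular_weight: float = 348000.0
    # CD block.
    run_cd: bool = True
    cd_helicity_base: float = 0.55
    cd_helicity_span: float = 0.15
    cd_noise_mdeg: float = 0.05
    melt_onset: float = 40.0
    melt_midpoint: float = 55.0
    melt_irreversible_fraction: float = 0.6
    make_figures: bool = False

    def validate(self) -> None:
        errors = []
        if self.simulate_xl and self.psm_tables:
            errors.append(
                "simulate_xl and psm_tables are both set: configure exactly "
                "one crosslink data source"
            )
        if not self.simulate_xl and not self.psm_tables:
            errors.append("no crosslink data source: set simulate_xl or psm_tables")
        if len(self.alleles) < 2:
            errors.append("alleles: need at least two for pairwise comparison")
        if self.simulate_xl is False and self.psm_tables:
            missing = [lab for lab, _ in self.alleles if lab not in self.psm_tables]
            if missing:
                errors.append(f"psm_tables: no table for allele(s) {missing}")
        if errors:
            raise ValueError("invalid run config:\n  - " + "\n  - ".join(errors))


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, caster in (
        ("sim_params", SimulationParams),
        ("criteria", FilterCriteria),
        ("thresholds", RangeThresholds),
    ):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = caster(**raw[key])
    for key in ("alleles",):
        if key in raw:
            raw[key] = tuple((str(a), int(q)) for a, q in raw[key])
    for key in ("hinge_interval", "ucd_interval", "geometry_dimensions"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        return [_json_ready(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 6)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    return obj


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    # Where outputs land (and whether figures are drawn) does not
    # affect any number; exclude so identical analyses hash alike.
    payload.pop("out_dir", None)
    payload.pop("make_figures", None)
    payload = json.dumps(_json_ready(payload), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _allele_contacts(config: RunConfig, out: Path) -> tuple[dict, dict, dict]:
    """Per-allele observed contact sets (+ per-allele stage counts and,
    in simulation mode, ground truth)."""
    contact_sets: dict[str, ContactSet] = {}
    stages: dict[str, dict] = {}
    truth: dict[str, dict] = {}

    models = {}
    if config.simulate_xl:
        base = build_solenoid_bead_model(
            chain_length=config.chain_length,
            landmarks=build_partition(
                config.chain_length,
                config.minor_site,
                config.hinge_interval,
                config.ucd_interval,
            ),
            params=config.sim_params,
            seed=config.seed,
        )
        for k, (label, polyq) in enumerate(config.alleles):
            models[label] = perturb_allele(base, polyq, seed=config.seed + k)
        truth["__lysine_mask__"] = base.lysine_mask

    for k, (label, _) in enumerate(config.alleles):
        if config.simulate_xl:
            sim = simulate_crosslinks(
                models[label],
                config.sim_params,
                allele_label=label,
                seed=config.seed * 1000 + k,
            )
            psms = sim.psms
            table_path = out / f"psms_{label}.tsv"
            write_psm_table(psms, table_path)
            truth[label] = {
                "n_true_detected": len(sim.true_contacts),
                "n_within_cutoff": len(sim.within_cutoff),
                "n_decoys": len(sim.decoys),
                "true_contacts": sim.true_contacts,
                "decoys": sim.decoys,
            }
            dropped = pd.DataFrame()
        else:
            psms, dropped = read_psm_table(config.psm_tables[label])
            if not dropped.empty:
                dropped.to_csv(out / f"dropped_{label}.csv", index=False)
        kept = apply_identification_filters(psms, config.criteria)
        pairs, self_links = collapse_to_site_pairs(kept)
        contact_sets[label] = ContactSet.from_pairs(label, pairs)
        stages[label] = {
            "n_psms": len(psms),
            "n_dropped_rows": int(len(dropped)),
            "n_pass_filter": len(kept),
            "n_self_links": len(self_links),
            "n_site_pairs": len(pairs),
            "categories": categorize_set(pairs, config.thresholds),
        }
        classification_table(pairs, config.thresholds).to_csv(
            out / f"contacts_{label}.csv", index=False
        )
    return contact_sets, stages, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle.

    The bundle's ``summary`` is also written to ``summary.json`` in the
    output directory and is bit-for-bit reproducible for a fixed seed
    and config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config %s seed %d", _config_hash(config), config.seed)

    contact_sets, stages, truth = _allele_contacts(config, out)
    labels = [label for label, _ in config.alleles]

    partition = build_partition(
        config.chain_length,
        config.minor_site,
        config.hinge_interval,
        config.ucd_interval,
    )

    # UCD detection from the union of short/mid-range observed contacts.
    detected_ucd: list[tuple[int, int]] = []
    lysine_mask = truth.get("__lysine_mask__")
    if config.detect_ucd and lysine_mask is not None:
        union_pairs = set().union(*(cs.pairs for cs in contact_sets.values()))
        from httxl.classify import classify_range

        kept_pairs = [
            p
            for p in union_pairs
            if classify_range(p, config.thresholds) in config.profile_categories
        ]
        profile = coverage_profile(
            kept_pairs,
            config.chain_length,
            window=config.profile_window,
            lysine_mask=lysine_mask,
        )
        detected_ucd = detect_uncrosslinked_region(profile)
        pd.DataFrame(
            {"residue": np.arange(1, config.chain_length + 1), "involvement": profile.counts}
        ).to_csv(out / "coverage_profile.csv", index=False)
        if detected_ucd:
            partition = build_partition(
                config.chain_length,
                config.minor_site,
                config.hinge_interval,
                detected_ucd[0],
            )

    partition.to_bed_like(out / "partition.txt")
    partition.to_json(out / "partition.json")

    pw = pairwise_matrix(list(contact_sets.values()))
    pw.to_csv(out / "pairwise_comparison.csv", index=False)

    domain_matrices = {}
    for label in labels:
        dm = domain_pair_summary(contact_sets[label], partition)
        dm.to_csv(out / f"domain_pairs_{label}.csv")
        domain_matrices[label] = dm

    geom = geometry_report(
        molecular_weight=config.molecular_weight,
        shape=config.geometry_shape,
        dimensions=config.geometry_dimensions,
        outer_volume=config.geometry_outer_volume,
    )

    cd_block = {}
    if config.run_cd:
        points = []
        for k, (label, polyq) in enumerate(config.alleles):
            spec = simulate_cd(
                helicity_level=config.cd_helicity_base
                + config.cd_helicity_span * (polyq - 2) / 76.0,
                noise_sd=config.cd_noise_mdeg,
                seed=config.seed * 100 + k,
                allele_label=label,
            )
            points.append((polyq, mre_at(spec, 222.0)))
        heat, cool = simulate_melt(
            onset=config.melt_onset,
            midpoint=config.melt_midpoint,
            irreversible_fraction=config.melt_irreversible_fraction,
            seed=config.seed,
        )
        melt = melt_summary(heat, cool)
        pd.DataFrame(
            {
                "temperature_C": np.concatenate([heat.temperature, cool.temperature]),
                "mre222": np.concatenate([heat.mre222, cool.mre222]),
                "direction": ["heating"] * len(heat.temperature)
                + ["cooling"] * len(cool.temperature),
            }
        ).to_csv(out / "melt_curves.csv", index=False)
        cd_block = {
            "mre222_vs_polyq": [[q, v] for q, v in points],
            "helicity_trend": helicity_trend(points),
            "melt": {
                "onset_C": melt.onset,
                "span_C": list(melt.span) if melt.span else None,
                "irreversibility_index": melt.irreversibility_index,
            },
        }

    summary = {
        "httxl_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "library_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "alleles": {label: stages[label] for label in labels},
        "pairwise": pw.to_dict(orient="records"),
        "partition": {
            "segments": [
                {"name": n, "start": s, "end": e} for n, s, e in partition.segments
            ],
            "detected_ucd_intervals": [list(iv) for iv in detected_ucd],
        },
        "domain_pair_counts": {
            label: domain_matrices[label].to_dict() for label in labels
        },
        "geometry": geom.as_dict(),
        "cd": cd_block,
    }
    if truth:
        summary["simulation_truth"] = {
            label: {
                k: v
                for k, v in truth[label].items()
                if k.startswith("n_")
            }
            for label in labels
        }
    summary = _json_ready(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    bundle = {
        "summary": summary,
        "contact_sets": contact_sets,
        "partition": partition,
        "pairwise": pw,
        "domain_matrices": domain_matrices,
        "truth": truth,
        "out_dir": str(out),
    }
    if config.make_figures:
        render_report(bundle, thresholds=config.thresholds)
    return bundle


def render_report(bundle: dict, thresholds: RangeThresholds | None = None) -> list[str]:
    """Human-readable summary + figures for a finished bundle.

    Returns the paths written. Figure failures degrade to the text
    report with a warning rather than aborting the run.
    """
    out = Path(bundle["out_dir"])
    written = []

    lines = ["httxl run summary", "================="]
    summary = bundle["summary"]
    for label, st in summary["alleles"].items():
        lines.append(
            f"{label}: {st['n_psms']} PSMs, {st['n_pass_filter']} pass filters, "
            f"{st['n_site_pairs']} unique site pairs "
            f"(short/mid/long = {st['categories']['short']}/"
            f"{st['categories']['mid']}/{st['categories']['long']})"
        )
    lines.append("")
    for row in summary["pairwise"]:
        lines.append(
            f"{row['allele_i']} vs {row['allele_j']}: shared {row['n_shared']}, "
            f"unique {row['n_unique_i']} / {row['n_unique_j']}"
        )
    lines.append("")
    seg = ", ".join(
        f"{s['name']} {s['start']}-{s['end']}" for s in summary["partition"]["segments"]
    )
    lines.append(f"partition: {seg}")
    g = summary["geometry"]
    lines.append(
        f"geometry: V = {g['outer_volume_A3']:.0f} A^3, "
        f"V_M = {g['vm_observed_A3_per_Da']:.2f} A^3/Da, "
        f"cavity ~{g['cavity_percent']}%"
    )
    if summary.get("cd"):
        melt = summary["cd"]["melt"]
        lines.append(
            f"CD: MRE222 slope {summary['cd']['helicity_trend']['slope']:.1f} "
            f"per Q; melt onset {melt['onset_C']} degC"
        )
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    written.append(str(report_path))

    try:
        from httxl import plots

        for label, cs in bundle["contact_sets"].items():
            fig_path = out / f"arcs_{label}.svg"
            plots.arc_diagram(
                cs,
                chain_length=bundle["partition"].chain_length,
                thresholds=thresholds,
                partition=bundle["partition"],
                path=fig_path,
            )
            written.append(str(fig_path))
    except Exception as exc:  # degrade to text-only
        warnings.warn(f"figure generation failed ({exc}); text report only")
    return written
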