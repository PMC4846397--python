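"""Ground-truth-bearing synthetic inputs for every pipeline stage.

The generator emulates the structural picture the analysis is built to
recover: a 3144-residue chain folded as a hollow, roughly spherical
solenoid (outer diameter ~115 Å) whose two arms meet near the protease
hinge (~residue 1219) with the chain termini in close proximity, an
extended peripheral span (~1800–2300) whose lysines are too far apart
to be crosslinked by DSS, and a polyglutamine-length-dependent shift of
the CTD-II arm toward CTD-I (with NTD-I easing away from CTD-I). DSS
crosslinks are drawn from lysine pairs within a Euclidean reach
(default 30 Å Cα–Cα: the reagent spacer plus two lysine side chains),
thinned by a detection probability, contaminated with distance-
violating decoys, and dressed with xQuest-style PSM attributes so that
true links overwhelmingly pass the identification filters and decoys
overwhelmingly fail.

Nothing here aspires to physical folding realism — the solenoid path is
a layered spherical spiral chosen for geometric plausibility (hollow
core, shell-like mass distribution, arm proximity) and full knowledge
of ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform

from httxl.cd import CDSpectrum, MeltCurve
from httxl.domains import DEFAULT_CHAIN_LENGTH, DomainPartition, build_partition
from httxl.xlink_io import CrosslinkPSM, SitePair

__all__ = [
    "SimulationParams",
    "BeadModel",
    "SimulatedCrosslinks",
    "build_solenoid_bead_model",
    "simulate_crosslinks",
    "perturb_allele",
    "random_psm_table",
    "simulate_cd",
    "simulate_melt",
    "helix_mre_template",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the forward model.

    crosslink_cutoff
        Maximum Cα–Cα Euclidean distance (Å) for a DSS link. 30 Å
        covers the 11.4 Å spacer plus two extended lysine side chains.
    p_detect
        Per-pair probability that a geometrically possible link is
        observed at all.
    fp_rate
        Expected distance-violating decoy pairs per detected true pair.
    psm_multiplicity
        Mean PSM count supporting one detected link (>= 1).
    min_separation
        Smallest sequence separation eligible for linking (tryptic
        peptides of adjacent lysines are still observable; only i == j
        and immediate neighbours are excluded).
    lysine_density
        Fraction of residues that are lysine when no sequence is given
        (huntingtin-like, ~3%).
    ctd2_rotation_deg / ctd2_shift_A
        Full-scale allelic displacement of the CTD-II arm: a rotation
        toward the CTD-I latitudes (degrees southward along meridians)
        plus a small radial approach (Å inward), reached at the longest
        tract (Q78) and zero at Q2.
    ntd1_rotation_deg / ntd1_shift_A
        Full-scale displacement of NTD-I away from CTD-I: northward
        rotation (degrees) plus outward radial shift (Å).
    """

    crosslink_cutoff: float = 30.0
    p_detect: float = 0.7
    fp_rate: float = 0.15
    psm_multiplicity: float = 1.6
    min_separation: int = 3
    lysine_density: float = 0.030
    outer_diameter: float = 115.0
    inner_void_radius: float = 35.0
    bead_spacing: float = 3.8
    ctd2_rotation_deg: float = 30.0
    ctd2_shift_A: float = 6.0
    ntd1_rotation_deg: float = 10.0
    ntd1_shift_A: float = 3.0
    allele_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.crosslink_cutoff <= 0:
            raise ValueError("crosslink cutoff must be positive")
        if not 0 <= self.p_detect <= 1:
            raise ValueError("p_detect must be a probability")
        if self.fp_rate < 0 or self.psm_multiplicity < 1:
            raise ValueError("fp_rate >= 0 and psm_multiplicity >= 1 required")


@dataclass
class BeadModel:
    """Per-residue Cα-level coordinates plus simulation ground truth."""

    coordinates: np.ndarray  # (chain_length, 3), Å
    lysine_mask: np.ndarray  # bool per residue
    chain_length: int
    hinge_residue: int
    domain_labels: np.ndarray  # per-residue segment name
    partition: DomainPartition
    params: SimulationParams
    rng_seed: int

    @property
    def lysine_positions(self) -> np.ndarray:
        """1-based residue indices of lysines."""
        return np.nonzero(self.lysine_mask)[0] + 1

    def to_pdb(self, path: str | Path) -> None:
        """Export the bead model as a Cα trace in PDB format."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n = self.chain_length
        atoms = struc.AtomArray(n)
        atoms.coord = self.coordinates.astype(np.float32)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.where(self.lysine_mask, "LYS", "ALA")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        atoms.hetero = np.zeros(n, dtype=bool)
        pdb_file = pdb.PDBFile()
        pdb_file.set_structure(atoms)
        pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Solenoid path construction


def _sph(r: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    return np.column_stack(
        (
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        )
    )


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _tune_turns(curve, target_len: float, lo: float = 0.05, hi: float = 400.0):
    """Solve for the turn count giving a path of the target length."""

    def gap(n: float) -> float:
        return _polyline_length(curve(n)) - target_len

    n = brentq(gap, lo, hi, xtol=1e-4)
    return curve(n), n


def _spiral(r, th0, th1, phi0, nturns, npts=6000, r1=None):
    t = np.linspace(0.0, 1.0, npts)
    theta = np.deg2rad(th0 + (th1 - th0) * t)
    rr = np.full(npts, float(r)) if r1 is None else r + (r1 - r) * t
    phi = phi0 + 2.0 * np.pi * nturns * t
    return _sph(rr, theta, phi), phi[-1]


def _updown_spiral(r, th_lo, th_hi, phi0, nturns, npts=8000):
    """θ runs th_hi → th_lo → th_hi while φ advances continuously."""
    t = np.linspace(0.0, 1.0, npts)
    tri = np.where(t < 0.5, 1.0 - 2.0 * t, 2.0 * t - 1.0)  # 1 → 0 → 1
    theta = np.deg2rad(th_lo + (th_hi - th_lo) * tri)
    phi = phi0 + 2.0 * np.pi * nturns * t
    return _sph(np.full(npts, float(r)), theta, phi), phi[-1]


def _connector(p0, p1, npts=60):
    t = np.linspace(0.0, 1.0, npts)[:, None]
    return p0 + (p1 - p0) * t


def _resample(polyline: np.ndarray, arc_positions: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    return np.column_stack(
        [np.interp(arc_positions, s, polyline[:, k]) for k in range(3)]
    )


def _build_coords(
    chain_length: int,
    partition: DomainPartition,
    params: SimulationParams,
    ntd1_dtheta: float = 0.0,  # degrees northward
    ntd1_dr: float = 0.0,  # Å outward
    ctd2_dtheta: float = 0.0,  # degrees southward (toward CTD-I)
    ctd2_dr: float = 0.0,  # Å inward
) -> np.ndarray:
    """Lay the chain along the hollow layered spherical spiral.

    The allele offsets reposition the NTD-I and CTD-II bands; each
    piece is re-tuned to its target arc length so bead spacing is
    preserved for every allele.
    """
    hinge_mid = partition.hinge_midpoint
    minor = partition.minor_site
    ucd_start, ucd_end = partition.ucd_interval
    spans = [
        (1, minor),  # NTD-I (outer shell, northern band)
        (minor + 1, hinge_mid),  # NTD-II (outer shell, southern band)
        (hinge_mid + 1, ucd_start - 1),  # CTD-I (inner shell, up & back)
        (ucd_start, ucd_end),  # UCD (peripheral south cap)
        (ucd_end + 1, chain_length),  # CTD-II (middle shell, returns north)
    ]
    scale = params.outer_diameter / 115.0
    r_ntd, r_ctd1, r_ucd_a, r_ucd_b, r_ctd2 = (
        53.0 * scale,
        45.0 * scale,
        51.0 * scale,
        47.0 * scale,
        51.0 * scale,
    )
    sp = params.bead_spacing

    pieces: list[np.ndarray] = []
    # NTD-I: north-polar band of the outer shell; its terminus sits at
    # the particle surface (antibody-accessible). The allelic offset
    # rotates the band away from the CTD-I latitudes.
    n_res = spans[0][1] - spans[0][0] + 1
    th0, th1 = 15.0 - ntd1_dtheta, 55.0 - ntd1_dtheta
    ntd1, _ = _tune_turns(
        lambda n: _spiral(r_ntd + ntd1_dr, th0, th1, 0.0, n)[0], n_res * sp
    )
    phi = np.arctan2(ntd1[-1, 1], ntd1[-1, 0])
    pieces.append(ntd1)

    # NTD-II: southern band of the outer shell, down to the hinge.
    n_res = spans[1][1] - spans[1][0] + 1
    start = _sph(np.array([r_ntd]), np.deg2rad(np.array([55.0])), np.array([phi]))[0]
    conn = _connector(ntd1[-1], start, npts=30)

    def ntd2_curve(n):
        spiral, _ = _spiral(r_ntd, 55.0, 95.0, phi, n)
        return np.vstack((conn, spiral))

    ntd2, _ = _tune_turns(ntd2_curve, n_res * sp)
    phi = np.arctan2(ntd2[-1, 1], ntd2[-1, 0])
    pieces.append(ntd2)

    # CTD-I: radial step inward at the hinge, then spiral up and back
    # on the inner shell's southern band.
    n_res = spans[2][1] - spans[2][0] + 1
    start = _sph(np.array([r_ctd1]), np.deg2rad(np.array([95.0])), np.array([phi]))[0]
    conn = _connector(ntd2[-1], start)

    def ctd1_curve(n):
        spiral, _ = _updown_spiral(r_ctd1, 50.0, 95.0, phi, n)
        return np.vstack((conn, spiral))

    ctd1, _ = _tune_turns(ctd1_curve, n_res * sp)
    phi = np.arctan2(ctd1[-1, 1], ctd1[-1, 0])
    pieces.append(ctd1)

    # UCD: cross the buffer gap onto the south cap, spiral in at one
    # radius and back out at another, then stop at the cap rim.
    n_res = spans[3][1] - spans[3][0] + 1
    cap_entry = _sph(
        np.array([r_ucd_a]), np.deg2rad(np.array([135.0])), np.array([phi + 0.5])
    )[0]
    conn = _connector(ctd1[-1], cap_entry, npts=90)

    def ucd_curve(n):
        down, phi_d = _spiral(r_ucd_a, 135.0, 176.0, phi + 0.5, n)
        up, _ = _spiral(r_ucd_b, 176.0, 135.0, phi_d, n)
        step = _connector(down[-1], up[0], npts=20)
        return np.vstack((conn, down, step, up))

    ucd, _ = _tune_turns(ucd_curve, n_res * sp)
    phi = np.arctan2(ucd[-1, 1], ucd[-1, 0])
    pieces.append(ucd)

    # CTD-II: climb back through the gap, transit quickly past the
    # CTD-I latitudes, then settle on a northern band of the middle
    # shell so the carboxyl terminus ends near the amino terminus. The
    # allelic offset rotates this band south toward CTD-I.
    n_res = spans[4][1] - spans[4][0] + 1
    r_c2 = r_ctd2 - ctd2_dr
    r_transit = 55.0 * scale  # outside the CTD-I shell, against NTD-II
    rim_exit = _sph(
        np.array([r_transit]), np.deg2rad(np.array([95.0])), np.array([phi + 0.5])
    )[0]
    conn = _connector(ucd[-1], rim_exit, npts=90)
    th_hi, th_lo = 55.0 + ctd2_dtheta, 8.0 + ctd2_dtheta

    def ctd2_curve(n):
        transit, phi_t = _spiral(
            r_transit, 95.0, th_hi, phi + 0.5, n / 40.0, npts=400, r1=r_c2
        )
        spiral, _ = _spiral(r_c2, th_hi, th_lo, phi_t, n)
        return np.vstack((conn, transit, spiral))

    ctd2, _ = _tune_turns(ctd2_curve, n_res * sp)
    pieces.append(ctd2)

    # Map residues onto the concatenated path: piece k's residues are
    # spread evenly over piece k's arc range, offset half a step from
    # each end so junction bonds match the in-piece spacing.
    lengths = [_polyline_length(p) for p in pieces]
    polyline = np.vstack(pieces)
    offsets = np.concatenate(([0.0], np.cumsum(lengths)))
    arc_positions = []
    for (a, b), off, L in zip(spans, offsets, lengths):
        n_res = b - a + 1
        arc_positions.append(off + (np.arange(n_res) + 0.5) / n_res * L)
    return _resample(polyline, np.concatenate(arc_positions))


def build_solenoid_bead_model(
    chain_length: int = DEFAULT_CHAIN_LENGTH,
    landmarks: DomainPartition | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
    lysine_sequence: str | None = None,
) -> BeadModel:
    """Lay the chain along a hollow layered spherical spiral.

    The amino-terminal arm spirals down an outer shell from near the
    north pole to the hinge; CTD-I spirals up and back on an inner
    shell; the UCD crosses a ~30 Å buffer gap onto a separated
    south-polar cap (peripheral and unreachable by DSS from the main
    body); CTD-II returns north on a middle shell so the carboxyl
    terminus ends near the amino terminus ("arm ends in proximity").
    The amino terminus sits on the outermost shell, reflecting its
    antibody accessibility at the particle surface.

    ``lysine_sequence``, if given, is a one-letter protein sequence used
    verbatim for the lysine mask; otherwise lysines are placed randomly
    at ``params.lysine_density``, except inside the UCD where they are
    placed by farthest-point selection at >= cutoff mutual distance
    (few lysine pairs within DSS reach — the planted depletion).
    """
    params = params or SimulationParams()
    partition = landmarks or build_partition(chain_length=chain_length)
    if partition.chain_length != chain_length:
        raise ValueError("landmark partition does not match chain length")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EAD]))
    ucd_start, ucd_end = partition.ucd_interval
    coords = _build_coords(chain_length, partition, params)

    if lysine_sequence is not None:
        if len(lysine_sequence) != chain_length:
            raise ValueError("sequence length does not match the chain length")
        mask = np.frombuffer(lysine_sequence.upper().encode(), dtype="S1") == b"K"
        mask = mask.copy()
    else:
        mask = np.zeros(chain_length, dtype=bool)
        non_ucd = np.concatenate(
            (np.arange(0, ucd_start - 1), np.arange(ucd_end, chain_length))
        )
        n_lys = int(round(params.lysine_density * non_ucd.size))
        mask[rng.choice(non_ucd, size=n_lys, replace=False)] = True
        # Planted depletion: UCD lysines kept >= cutoff apart in space,
        # placed by farthest-point greedy so they span the whole cap.
        # Candidates exclude the ~25-residue gap-transit edges, which
        # pass between the cap and the main body rather than lying in
        # the extended span itself.
        lo_cand, hi_cand = ucd_start - 1 + 25, ucd_end - 1 - 25
        candidates = np.arange(lo_cand, hi_cand + 1)
        target = int(round(params.lysine_density * (ucd_end - ucd_start + 1)))
        spacing = params.crosslink_cutoff + 2.0
        # Anchor both ends of the span, then spread the rest by
        # farthest-point greedy with the mutual-spacing constraint;
        # every accepted point is >= spacing from all previous ones,
        # so the planted span carries no within-cutoff lysine pair.
        chosen = [int(lo_cand), int(hi_cand)]
        cand_xyz = coords[candidates]
        min_dist = np.min(
            np.linalg.norm(cand_xyz[:, None, :] - coords[chosen], axis=2), axis=1
        )
        while len(chosen) < target and min_dist.max() >= spacing:
            nxt = int(np.argmax(min_dist))
            chosen.append(int(candidates[nxt]))
            min_dist = np.minimum(
                min_dist, np.linalg.norm(cand_xyz - cand_xyz[nxt], axis=1)
            )
        mask[chosen] = True

    return BeadModel(
        coordinates=coords,
        lysine_mask=mask,
        chain_length=chain_length,
        hinge_residue=partition.hinge_midpoint,
        domain_labels=partition.labels(),
        partition=partition,
        params=params,
        rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Allelic perturbation


def polyq_fraction(polyq_length: int) -> float:
    """Normalized tract length: 0 at Q2, 1 at Q78."""
    if polyq_length < 2:
        raise ValueError("polyglutamine tract length must be >= 2")
    return min(1.0, (polyq_length - 2) / 76.0)


def perturb_allele(
    model: BeadModel,
    polyq_length: int,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> BeadModel:
    """Tract-length-dependent conformational shift of the arms.

    The CTD-II arm rotates along meridians toward the CTD-I band (and
    approaches it slightly in radius), producing monotonically more
    CTD-II↔CTD-I proximity as the tract lengthens; NTD-I rotates and
    shifts away from CTD-I, producing fewer NTD-I↔CTD-I contacts.
    Displacements are linear in the normalized tract length. The
    displaced pieces are regenerated (not transformed pointwise) with
    their arc lengths re-tuned, so bead spacing is preserved for every
    allele; the lysine mask is carried over unchanged — the alleles are
    the same protein. With the displacement scales at zero (or a Q2
    tract) the model is returned unchanged. The optional seed drives
    coordinate jitter only when ``allele_jitter_sd`` > 0.
    """
    params = params or model.params
    q = polyq_fraction(polyq_length)
    coords = _build_coords(
        model.chain_length,
        model.partition,
        params,
        ntd1_dtheta=params.ntd1_rotation_deg * q,
        ntd1_dr=params.ntd1_shift_A * q,
        ctd2_dtheta=params.ctd2_rotation_deg * q,
        ctd2_dr=params.ctd2_shift_A * q,
    )

    if params.allele_jitter_sd > 0 and seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11]))
        coords = coords + rng.normal(0.0, params.allele_jitter_sd, coords.shape)

    return replace_coords(model, coords)


def replace_coords(model: BeadModel, coords: np.ndarray) -> BeadModel:
    return BeadModel(
        coordinates=coords,
        lysine_mask=model.lysine_mask,
        chain_length=model.chain_length,
        hinge_residue=model.hinge_residue,
        domain_labels=model.domain_labels,
        partition=model.partition,
        params=model.params,
        rng_seed=model.rng_seed,
    )


# ---------------------------------------------------------------------------
# Crosslink observation model


@dataclass
class SimulatedCrosslinks:
    """PSM table plus the ground truth it was drawn from."""

    psms: list[CrosslinkPSM]
    true_contacts: frozenset[SitePair]  # detected, within-cutoff pairs
    within_cutoff: frozenset[SitePair]  # every geometrically possible pair
    decoys: frozenset[SitePair]  # planted distance-violating pairs
    allele_label: str


def _true_attributes(rng: np.random.Generator) -> dict:
    return {
        "score": float(max(1.0, rng.normal(28.0, 5.0))),
        "delta_score": float(rng.beta(2.0, 6.0)),
        "mass_error": float(rng.normal(0.0, 1.5)),
        "tic_fraction": float(max(0.02, rng.normal(0.35, 0.10))),
        "min_bond_cleavages": int(4 + rng.poisson(2.0)),
        "peptide_len_a": int(rng.integers(6, 26)),
        "peptide_len_b": int(rng.integers(6, 26)),
    }


def _decoy_attributes(rng: np.random.Generator) -> dict:
    return {
        "score": float(max(0.5, rng.normal(11.0, 3.0))),
        "delta_score": float(rng.uniform(0.4, 1.05)),
        "mass_error": float(rng.normal(0.0, 2.5)),
        "tic_fraction": float(max(0.01, rng.normal(0.20, 0.10))),
        "min_bond_cleavages": int(rng.integers(2, 8)),
        "peptide_len_a": int(rng.integers(4, 21)),
        "peptide_len_b": int(rng.integers(4, 21)),
    }


def simulate_crosslinks(
    model: BeadModel,
    params: SimulationParams | None = None,
    allele_label: str = "Q23",
    seed: int = 0,
) -> SimulatedCrosslinks:
    """Forward model of the DSS XL-MS observation process.

    True links are the lysine pairs within the Euclidean cutoff (at
    sequence separation >= ``min_separation``); each is detected with
    probability ``p_detect`` and supported by ~``psm_multiplicity``
    PSMs with attributes drawn from the passing regime. Decoy pairs are
    drawn uniformly from beyond-cutoff lysine pairs at ``fp_rate`` per
    detected true pair, with attributes drawn from the failing regime.
    """
    params = params or model.params
    lys = model.lysine_positions
    if lys.size == 0:
        raise ValueError("bead model has no lysines")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0DE]))

    dists = squareform(pdist(model.coordinates[lys - 1]))
    ii, jj = np.triu_indices(lys.size, k=1)
    sep_ok = (lys[jj] - lys[ii]) >= params.min_separation
    close = dists[ii, jj] <= params.crosslink_cutoff
    true_pairs = [
        (int(lys[a]), int(lys[b]))
        for a, b in zip(ii[close & sep_ok], jj[close & sep_ok])
    ]
    far_pairs = [
        (int(lys[a]), int(lys[b]))
        for a, b in zip(ii[~close & sep_ok], jj[~close & sep_ok])
    ]

    detected = [p for p in true_pairs if rng.random() < params.p_detect]
    n_decoys = int(rng.poisson(params.fp_rate * max(len(detected), 1)))
    n_decoys = min(n_decoys, len(far_pairs))
    decoy_idx = rng.choice(len(far_pairs), size=n_decoys, replace=False)
    decoys = [far_pairs[k] for k in decoy_idx]

    psms: list[CrosslinkPSM] = []
    spectrum = 0
    support: dict[tuple[int, int], int] = {}
    for i, j in detected:
        n_psm = 1 + int(rng.poisson(params.psm_multiplicity - 1.0))
        support[(i, j)] = n_psm
        for _ in range(n_psm):
            spectrum += 1
            a, b = (i, j) if rng.random() < 0.5 else (j, i)
            psms.append(
                CrosslinkPSM(
                    allele_label=allele_label,
                    spectrum_id=f"{allele_label}.{spectrum:05d}",
                    site_a=a,
                    site_b=b,
                    **_true_attributes(rng),
                )
            )
    for i, j in decoys:
        spectrum += 1
        psms.append(
            CrosslinkPSM(
                allele_label=allele_label,
                spectrum_id=f"{allele_label}.{spectrum:05d}",
                site_a=i,
                site_b=j,
                **_decoy_attributes(rng),
            )
        )
    order = rng.permutation(len(psms))
    psms = [psms[k] for k in order]

    return SimulatedCrosslinks(
        psms=psms,
        true_contacts=frozenset(
            SitePair(i, j, support[(i, j)]) for i, j in detected
        ),
        within_cutoff=frozenset(SitePair(i, j) for i, j in true_pairs),
        decoys=frozenset(SitePair(i, j) for i, j in decoys),
        allele_label=allele_label,
    )


def random_psm_table(n: int, seed: int = 0, allele_label: str = "Q23") -> list[CrosslinkPSM]:
    """PSMs with attributes straddling every filter threshold.

    A stress input for filter testing: each attribute is drawn from a
    wide range crossing its criterion boundary, so roughly half the
    rows fail at least one criterion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF117]))
    psms = []
    for k in range(n):
        i = int(rng.integers(1, 3144))
        j = int(rng.integers(1, 3145))
        psms.append(
            CrosslinkPSM(
                allele_label=allele_label,
                spectrum_id=f"{allele_label}.r{k:05d}",
                score=float(rng.uniform(5.0, 40.0)),
                delta_score=float(rng.uniform(0.0, 1.2)),
                mass_error=float(rng.uniform(-6.0, 6.0)),
                tic_fraction=float(rng.uniform(0.0, 0.6)),
                min_bond_cleavages=int(rng.integers(1, 9)),
                peptide_len_a=int(rng.integers(4, 26)),
                peptide_len_b=int(rng.integers(4, 26)),
                site_a=i,
                site_b=j,
            )
        )
    return psms


# ---------------------------------------------------------------------------
# Synthetic CD spectra and melt curves


def helix_mre_template(wavelength: np.ndarray) -> np.ndarray:
    """α-helix-like MRE curve: minima at 208 and 222 nm, peak at 195 nm.

    An empirical two-Gaussian-minimum template (deg·cm²/dmol at full
    helicity), not a basis-set spectrum.
    """
    wl = np.asarray(wavelength, dtype=float)
    return (
        -36000.0 * np.exp(-((wl - 222.0) ** 2) / (2 * 5.5**2))
        - 35000.0 * np.exp(-((wl - 208.0) ** 2) / (2 * 4.0**2))
        + 60000.0 * np.exp(-((wl - 195.0) ** 2) / (2 * 3.5**2))
    )


def simulate_cd(
    helicity_level: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    allele_label: str = "",
    concentration: float = 0.2,
    path_length: float = 0.1,
    n_residues: int = DEFAULT_CHAIN_LENGTH,
    molecular_weight: float = 348000.0,
) -> CDSpectrum:
    """Far-UV scan (185–260 nm) of a partially helical protein.

    The helix template is scaled by ``helicity_level`` (1 = template
    amplitude, 0 = featureless), converted to raw millidegrees with the
    stated cell metadata, and dressed with Gaussian noise (mdeg).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCD]))
    wl = np.arange(185.0, 261.0, 1.0)
    mre = helicity_level * helix_mre_template(wl)
    mrw = molecular_weight / (n_residues - 1)
    mdeg = mre * (10.0 * path_length * concentration) / mrw
    if noise_sd > 0:
        mdeg = mdeg + rng.normal(0.0, noise_sd, wl.shape)
    return CDSpectrum(
        wavelength=wl,
        ellipticity=mdeg,
        concentration=concentration,
        path_length=path_length,
        n_residues=n_residues,
        molecular_weight=molecular_weight,
        allele_label=allele_label,
    )


def simulate_melt(
    onset: float = 40.0,
    midpoint: float = 55.0,
    irreversible_fraction: float = 0.6,
    seed: int = 0,
    noise_sd: float = 50.0,
    baseline_mre: float = -20000.0,
    plateau_mre: float = -2000.0,
    t_min: float = 25.0,
    t_max: float = 95.0,
    step: float = 5.0,
) -> tuple[MeltCurve, MeltCurve]:
    """Heating and cooling melt curves at 222 nm.

    Heating: flat at ``baseline_mre`` up to ``onset``, then a
    raised-cosine loss centred at ``midpoint`` reaching ``plateau_mre``
    (the denatured/aggregated signal). Cooling retraces only
    ``1 − irreversible_fraction`` of the transition — at 1 the
    denaturation is fully irreversible; at 0 cooling reproduces heating
    exactly.
    """
    if not 0 <= irreversible_fraction <= 1:
        raise ValueError("irreversible fraction must be in [0, 1]")
    if midpoint <= onset:
        raise ValueError("midpoint must lie above the onset")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3317]))
    temps = np.arange(t_min, t_max + step / 2, step)
    t_done = onset + 2.0 * (midpoint - onset)
    frac = np.clip((temps - onset) / (t_done - onset), 0.0, 1.0)
    s = 0.5 * (1.0 - np.cos(np.pi * frac))
    heat_mre = baseline_mre + (plateau_mre - baseline_mre) * s
    final = heat_mre[-1]
    cool_mre = irreversible_fraction * final + (1.0 - irreversible_fraction) * heat_mre
    if noise_sd > 0:
        heat_mre = heat_mre + rng.normal(0.0, noise_sd, temps.shape)
        cool_mre = cool_mre + rng.normal(0.0, noise_sd, temps.shape)
        cool_mre[-1] = heat_mre[-1]  # both curves share the 95 °C read
    heat = MeltCurve(temperature=temps, mre222=heat_mre, direction="heating")
    cool = MeltCurve(
        temperature=temps[::-1], mre222=cool_mre[::-1], direction="cooling"
    )
    return heat, cool
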