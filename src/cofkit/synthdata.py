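"""Seeded generators producing inputs with known ground truth.

Every analysis module in the package has a matching generator here: toy
binding pockets with hydrogen-bond donors planted at exact out-of-plane
offsets and octahedral Mg2+ sites, ligand-pose pairs related by a known
rotation about the carboxylate O--O axis, homolog sequence sets with a
planted diagnostic column, triplicate chromatogram time courses with
known product-formation rates, and two-state melting curves with known
dissociation constants.

All randomness flows through one ``numpy.random.default_rng(seed)``
stream per generator call; the seed is mandatory (part of each spec), so
identical specs reproduce identical outputs byte for byte.  Chemical
realism is not a goal -- geometric and kinetic ground truth is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from .alignscreen import AlignedRow, MultipleAlignment, SequenceRecord
from .assayquant import (
    SUBSTRATE_PRODUCT_MAP,
    ChromatogramRun,
    ChromatogramSet,
)
from .dsfbind import MeltingCurve, UnfoldingModel, predict_signal
from .errors import SpecError
from .structgeom import Atom, StructureModel

__all__ = [
    "PocketSpec",
    "HomologSetSpec",
    "AssaySimSpec",
    "DSFSimSpec",
    "CARBOXYLATE_TEMPLATE",
    "GPPG_LIKE_TEMPLATE",
    "make_pocket",
    "make_ligand_pair",
    "make_homolog_set",
    "make_assay_run",
    "make_dsf_curves",
    "DEFAULT_SPECIES_MZ",
    "DEFAULT_PEAK_RT",
    "default_species_params",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# idealized sp2 carboxylate: C1 carboxyl carbon at the origin in the z=0
# plane, 1.25 A C-O bonds 120 deg apart, 1.52 A bond to the alpha carbon C2
_CO = 1.25
_CC = 1.52
CARBOXYLATE_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (0.0, 0.0, 0.0)),
    ("O1", "O", (_CO * math.cos(math.radians(60)), _CO * math.sin(math.radians(60)), 0.0)),
    ("O2", "O", (_CO * math.cos(math.radians(-60)), _CO * math.sin(math.radians(-60)), 0.0)),
    ("C2", "C", (-_CC, 0.0, 0.0)),
]

# a schematic glycerate + diphosphate arm (1.6 A P-O bonds, tetrahedral-ish
# phosphates); only the carboxylate end carries geometric ground truth
GPPG_LIKE_TEMPLATE: list[tuple[str, str, tuple[float, float, float]]] = [
    *CARBOXYLATE_TEMPLATE,
    ("O2'", "O", (-2.0, 1.2, 0.5)),
    ("C3", "C", (-2.3, -0.9, -0.6)),
    ("O3", "O", (-3.7, -1.0, -0.6)),
    ("P1", "P", (-4.6, -2.2, -1.1)),
    ("O11", "O", (-4.3, -3.5, -0.4)),
    ("O12", "O", (-4.5, -2.4, -2.7)),
    ("O13", "O", (-6.1, -1.8, -0.8)),
    ("P2", "P", (-7.3, -2.8, -1.2)),
    ("O21", "O", (-7.2, -4.1, -0.5)),
    ("O22", "O", (-7.4, -3.0, -2.8)),
    ("O23", "O", (-8.6, -2.0, -0.8)),
    ("C4", "C", (-9.9, -2.6, -1.1)),
]


@dataclass
class PocketSpec:
    """Toy binding pocket: planted H-bond offsets, metals, chains."""

    n_donors: int = 2
    planted_pi_offsets: tuple[float, ...] = (0.74, 0.74)
    ligand_template: str = "carboxylate-only"   # or "GPPG-like"
    n_metals: int = 0
    chains: int = 1
    jitter_sd: float = 0.0
    seed: int = 0
    hbond_distance: float = 2.9
    max_hbond_distance: float = 3.5

    def __post_init__(self):
        if self.n_donors != len(self.planted_pi_offsets):
            raise SpecError("n_donors must match planted_pi_offsets length")
        if any(o < 0 for o in self.planted_pi_offsets):
            raise SpecError("planted offsets must be >= 0")
        if self.chains < 1:
            raise SpecError("at least one chain required")
        if self.ligand_template not in ("carboxylate-only", "GPPG-like"):
            raise SpecError(f"unknown ligand template {self.ligand_template!r}")


@dataclass
class HomologSetSpec:
    """Homolog sequences with a planted diagnostic residue per homolog."""

    reference_length: int = 180
    n_homologs: int = 6
    substitution_rate: float = 0.05
    diagnostic_position: int = 162
    planted_labels: tuple[str, ...] = ("S", "T", "G", "A", "S", "G")
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.diagnostic_position <= self.reference_length:
            raise SpecError("diagnostic position outside the reference")
        if len(self.planted_labels) != self.n_homologs:
            raise SpecError("one planted label per homolog required")
        if not 0 <= self.substitution_rate < 1:
            raise SpecError("substitution_rate must lie in [0, 1)")


@dataclass
class AssaySimSpec:
    """Competitive CofC/D assay: linear product formation, then saturation."""

    true_rates: dict[str, float] = field(
        default_factory=lambda: {"3-PG": 0.65, "2-PL": 0.265, "PEP": 0.085})
    time_points: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0)
    saturation_after: float = 20.0
    peak_width: float = 0.08          # Gaussian sigma, min
    noise_cv: float = 0.02
    n_replicates: int = 3
    seed: int = 0
    n_rt_points: int = 81

    def __post_init__(self):
        if any(r < 0 for r in self.true_rates.values()):
            raise SpecError("rates must be >= 0")
        if any(t < 0 for t in self.time_points):
            raise SpecError("time points must be >= 0")


@dataclass
class DSFSimSpec:
    """Melting-curve series generated from the two-state linkage model."""

    t_m: float = 320.0                # K
    delta_h_u: float = 300.0          # kJ/mol
    k_d_gtp: float = 1e-5             # M
    k_d_gppg: float | None = None
    phi_gppg: float = 0.0
    a_n: float = 1.5
    b_n: float = -0.001
    a_u: float = 0.5
    b_u: float = 0.004
    ligand_concs: tuple[float, ...] = (0.0, 2e-6, 5e-6, 1e-5, 2e-5, 5e-5, 2e-4)
    temperatures: tuple[float, float, float] = (293.0, 363.0, 0.5)   # K: lo, hi, step
    protein_conc: float = 1e-5
    noise_sd: float = 0.0
    seed: int = 0

    def model(self) -> UnfoldingModel:
        return UnfoldingModel(t_m=self.t_m, delta_h_u=self.delta_h_u,
                              a_n=self.a_n, b_n=self.b_n,
                              a_u=self.a_u, b_u=self.b_u,
                              k_d_gtp=self.k_d_gtp, k_d_gppg=self.k_d_gppg,
                              phi_gppg=self.phi_gppg)


# ---------------------------------------------------------------------------
# pockets and ligand pairs
# ---------------------------------------------------------------------------

def _ligand_atoms(template: str) -> list[tuple[str, str, tuple[float, float, float]]]:
    return (CARBOXYLATE_TEMPLATE if template == "carboxylate-only"
            else GPPG_LIKE_TEMPLATE)


def make_pocket(spec: PocketSpec) -> tuple[StructureModel, dict]:
    """Build a toy pocket with donors at exact out-of-plane offsets.

    Each donor is a protein nitrogen placed against a carboxylate oxygen
    of the ligand at heavy-atom distance ``hbond_distance`` (inflated when
    a large offset demands it) and exactly its planted offset out of the
    carboxylate plane.  Optional Mg2+ ions sit >10 A away with octahedral
    water shells.  Chain A is exact; further chains are translated copies
    with seeded Gaussian jitter of ``jitter_sd``.  The returned truth
    table lists every planted H-bond, offset and metal.
    """
    rng = np.random.default_rng(spec.seed)
    lig_template = _ligand_atoms(spec.ligand_template)
    lig_res_name = "CBX" if spec.ligand_template == "carboxylate-only" else "GPG"
    coords = {n: np.array(c) for n, _, c in lig_template}
    c1, o1, o2 = coords["C1"], coords["O1"], coords["O2"]
    normal = np.array([0.0, 0.0, 1.0])           # carboxylate plane is z = 0

    donors = []   # (target oxygen name, position, offset, distance)
    for i, off in enumerate(spec.planted_pi_offsets):
        d = spec.hbond_distance
        if off >= d:
            d = math.sqrt(off ** 2 + 1.0)
        if d > spec.max_hbond_distance:
            raise SpecError(f"offset {off} A cannot fit inside the "
                            f"{spec.max_hbond_distance} A H-bond cutoff")
        rho = math.sqrt(d ** 2 - off ** 2)
        o_name = "O1" if i % 2 == 0 else "O2"
        o = coords[o_name]
        u = (o - c1) / np.linalg.norm(o - c1)    # in-plane, points outward
        # fan successive donors on the same oxygen apart within the plane
        ang = math.radians(28.0 * (i // 2)) * (1 if o_name == "O1" else -1)
        rot = Rotation.from_rotvec(normal * ang)
        u = rot.apply(u)
        pos = o + rho * u + off * normal
        donors.append((o_name, pos, off, d))

    metals = []   # (mg position, [water positions])
    for i in range(spec.n_metals):
        center = np.array([14.0 + 7.0 * i, 0.0, 0.0])
        shell = [center + 2.1 * v
                 for v in np.vstack([np.eye(3), -np.eye(3)])]
        metals.append((center, shell))

    chain_ids = [chr(ord("A") + i) for i in range(spec.chains)]
    atoms: list[Atom] = []
    serial = 1

    def add(name, element, pos, chain, res_name, res_num, hetero):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element,
                          alt_loc="", chain=chain, res_name=res_name,
                          res_num=res_num, insertion_code="",
                          coords=tuple(float(x) for x in pos),
                          occupancy=1.0, is_hetero=hetero))
        serial += 1

    for ci, chain in enumerate(chain_ids):
        shift = np.array([0.0, 60.0 * ci, 0.0])

        def place(p):
            p = np.asarray(p) + shift
            if ci > 0 and spec.jitter_sd > 0:
                p = p + rng.normal(0.0, spec.jitter_sd, size=3)
            return p

        for i, (o_name, pos, off, dist) in enumerate(donors):
            add("N", "N", place(pos), chain, "GLY", 10 + i, hetero=False)
        for name, element, c in lig_template:
            add(name, element, place(np.asarray(c)), chain, lig_res_name, 501,
                hetero=True)
        for mi, (center, shell) in enumerate(metals):
            add("MG", "Mg", place(center), chain, "MG", 601 + mi, hetero=True)
            for wi, w in enumerate(shell):
                add("O", "O", place(w), chain, "HOH",
                    701 + mi * 10 + wi, hetero=True)

    truth = {
        "ligand": ("A", lig_res_name, 501),
        "ligand_res_name": lig_res_name,
        "chains": chain_ids,
        "hbonds": [
            {"chain": "A", "donor_res_num": 10 + i, "donor_atom": "N",
             "acceptor_atom": o_name, "pi_offset": off, "heavy_distance": dist}
            for i, (o_name, _, off, dist) in enumerate(donors)
        ],
        "mean_pi_offset": (float(np.mean(spec.planted_pi_offsets))
                           if spec.planted_pi_offsets else None),
        "metals": [
            {"res_num": 601 + mi, "n_coordinating": len(shell),
             "shell_distance": 2.1}
            for mi, (_, shell) in enumerate(metals)
        ],
    }
    model = StructureModel(atoms=atoms, title="cofkit synthetic pocket",
                           source_id="SYNTH")
    return model, truth


def make_ligand_pair(base_ligand=None, rotation_deg: float = 36.0,
                     displacement_target_atom: str = "P1",
                     axis_oxygens: tuple[str, str] = ("O1", "O2"),
                     ) -> tuple[dict, dict, dict]:
    """Two ligand poses related by an exact rotation about the O--O axis.

    Returns coordinate dicts (atom name -> 3-vector) for the base pose,
    the rotated pose, and a truth record with the folded angle and
    per-atom displacements.
    """
    if base_ligand is None:
        base_ligand = {n: np.array(c) for n, _, c in GPPG_LIKE_TEMPLATE}
    lig_a = {n: np.asarray(c, dtype=float) for n, c in base_ligand.items()}
    for name in (*axis_oxygens, displacement_target_atom):
        if name not in lig_a:
            raise SpecError(f"base ligand lacks atom {name!r}")
    o1, o2 = lig_a[axis_oxygens[0]], lig_a[axis_oxygens[1]]
    axis = o2 - o1
    n = np.linalg.norm(axis)
    if n < 1e-6:
        raise SpecError("axis oxygens coincide")
    axis = axis / n
    mid = (o1 + o2) / 2.0
    rot = Rotation.from_rotvec(axis * math.radians(rotation_deg))
    lig_b = {name: mid + rot.apply(p - mid) for name, p in lig_a.items()}
    folded = abs(rotation_deg) % 360.0
    if folded > 180.0:
        folded = 360.0 - folded
    truth = {
        "angle_deg": folded,
        "axis": axis,
        "displacements": {name: float(np.linalg.norm(lig_b[name] - lig_a[name]))
                          for name in lig_a},
        "target_displacement": float(np.linalg.norm(
            lig_b[displacement_target_atom] - lig_a[displacement_target_atom])),
    }
    return lig_a, lig_b, truth


# ---------------------------------------------------------------------------
# homolog sets
# ---------------------------------------------------------------------------

def make_homolog_set(spec: HomologSetSpec,
                     ) -> tuple[list[SequenceRecord], MultipleAlignment, dict]:
    """Reference + homologs with a planted diagnostic column.

    Homologs are i.i.d. substitutions of the reference away from the
    diagnostic position, whose residue is forced to the planted label.
    Seeded single-residue deletions (gaps in the homolog row) and
    insertions (gap columns in every other row) shape the true alignment.
    Truth labels follow the serine/threonine tolerance rule.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.reference_length
    diag = spec.diagnostic_position
    ref = [_AA[i] for i in rng.integers(0, len(_AA), size=L)]
    ref[diag - 1] = "S"

    # events per homolog: substitutions, deletions, insertions-after
    homolog_cols: list[list[str]] = []
    insertions: list[dict[int, str]] = []
    for h in range(spec.n_homologs):
        row = []
        ins: dict[int, str] = {}
        for pos in range(1, L + 1):
            ch = ref[pos - 1]
            if pos == diag:
                ch = spec.planted_labels[h]
            else:
                if rng.random() < spec.gap_rate / 2.0:
                    ch = "-"                       # deletion
                elif rng.random() < spec.substitution_rate:
                    choices = _AA.replace(ref[pos - 1], "")
                    ch = choices[rng.integers(0, len(choices))]
                if rng.random() < spec.gap_rate / 2.0 and pos != diag:
                    ins[pos] = _AA[rng.integers(0, len(_AA))]
            row.append(ch)
        homolog_cols.append(row)
        insertions.append(ins)

    # assemble alignment columns: reference position columns interleaved
    # with one extra column per (homolog, position) insertion event
    aln_cols: list[list[str]] = []
    for pos in range(1, L + 1):
        col = [ref[pos - 1]] + [homolog_cols[h][pos - 1]
                                for h in range(spec.n_homologs)]
        aln_cols.append(col)
        for h in range(spec.n_homologs):
            if pos in insertions[h]:
                ins_col = ["-"] * (spec.n_homologs + 1)
                ins_col[h + 1] = insertions[h][pos]
                aln_cols.append(ins_col)

    mat = np.array(aln_cols).T    # rows x columns
    ids = ["REF"] + [f"H{h + 1:02d}" for h in range(spec.n_homologs)]
    aligned = [AlignedRow(ids[i], ids[i], "".join(mat[i])) for i in range(len(ids))]
    alignment = MultipleAlignment(aligned)

    records = [r.degapped() for r in aligned]
    # the reference row gains gaps only from insertion columns, so the
    # diagnostic column is where its diag-th residue landed
    count = 0
    diag_col = -1
    for col, ch in enumerate(aligned[0].residues, start=1):
        if ch != "-":
            count += 1
            if count == diag:
                diag_col = col
                break
    labels = {f"H{h + 1:02d}": ("tolerant" if spec.planted_labels[h] in ("S", "T")
                                else "non_tolerant")
              for h in range(spec.n_homologs)}
    labels["REF"] = "tolerant"
    truth = {
        "diagnostic_column": diag_col,
        "diagnostic_position": diag,
        "labels": labels,
        "planted_residues": {f"H{h + 1:02d}": spec.planted_labels[h]
                             for h in range(spec.n_homologs)},
    }
    return records, alignment, truth


# ---------------------------------------------------------------------------
# assay chromatograms
# ---------------------------------------------------------------------------

#: arbitrary but fixed instrument-like parameters for the product species
DEFAULT_SPECIES_MZ = {"3PG-F420-0": 789.2, "F420-0": 773.2,
                      "DF420-0": 771.2, "FO": 364.1}
DEFAULT_PEAK_RT = {"3PG-F420-0": 4.8, "F420-0": 5.2,
                   "DF420-0": 5.6, "FO": 6.5}


def default_species_params(spec: AssaySimSpec) -> dict[str, dict]:
    """Per-species m/z targets and rt windows matching the generator."""
    params = {}
    for sub in spec.true_rates:
        sp = SUBSTRATE_PRODUCT_MAP.get(sub, sub)
        rt = DEFAULT_PEAK_RT[sp]
        params[sp] = {"mz_target": DEFAULT_SPECIES_MZ[sp], "mz_tol": 0.5,
                      "rt_window": (rt - 4 * spec.peak_width,
                                    rt + 4 * spec.peak_width)}
    return params


def make_assay_run(spec: AssaySimSpec) -> tuple[ChromatogramSet, dict]:
    """Simulate triplicate chromatogram time courses with known rates.

    Per replicate, reaction time and product species, a Gaussian peak is
    written whose area is ``rate * min(t, saturation_after)`` perturbed by
    multiplicative Gaussian noise of CV ``noise_cv``.  Peaks share one
    retention-time sampling density, so quadrature error cancels exactly
    in area *ratios*.  Truth records the rates and the expected relative
    turnover per substrate.
    """
    rng = np.random.default_rng(spec.seed)
    runs = []
    for r in range(spec.n_replicates):
        rep = f"rep{r + 1}"
        for t in spec.time_points:
            traces = {}
            for sub in sorted(spec.true_rates):
                sp = SUBSTRATE_PRODUCT_MAP.get(sub, sub)
                rate = spec.true_rates[sub]
                area = rate * min(t, spec.saturation_after)
                if spec.noise_cv > 0:
                    area *= 1.0 + rng.normal(0.0, spec.noise_cv)
                area = max(area, 0.0)
                rt0 = DEFAULT_PEAK_RT[sp]
                rt = np.linspace(rt0 - 4 * spec.peak_width,
                                 rt0 + 4 * spec.peak_width, spec.n_rt_points)
                inten = area * norm.pdf(rt, rt0, spec.peak_width)
                traces[sp] = pd.DataFrame({
                    "rt_min": rt,
                    "mz": np.full_like(rt, DEFAULT_SPECIES_MZ[sp]),
                    "intensity": inten,
                })
            runs.append(ChromatogramRun(rep, float(t), traces))
    total = sum(spec.true_rates.values())
    truth = {
        "rates": dict(spec.true_rates),
        "expected_percent": {sub: 100.0 * k / total
                             for sub, k in spec.true_rates.items()},
        "substrate_map": {sub: SUBSTRATE_PRODUCT_MAP.get(sub, sub)
                          for sub in spec.true_rates},
    }
    return ChromatogramSet(runs), truth


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def make_dsf_curves(spec: DSFSimSpec) -> tuple[list[MeltingCurve], dict]:
    """Melting-curve series from the forward model plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    model = spec.model()
    lo, hi, step = spec.temperatures
    T = np.arange(lo, hi + step / 2, step)
    curves = []
    for L in spec.ligand_concs:
        sig = predict_signal(model, T, L, spec.protein_conc)
        if spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
        curves.append(MeltingCurve(float(L), np.column_stack([T, sig]),
                                   spec.protein_conc))
    truth = {
        "t_m": spec.t_m, "delta_h_u": spec.delta_h_u,
        "k_d_gtp": spec.k_d_gtp, "k_d_gppg": spec.k_d_gppg,
        "phi_gppg": spec.phi_gppg,
    }
    return curves, truth


def dsf_curves_to_csv(curves: list[MeltingCurve]) -> str:
    """Serialize curves to the long CSV schema read by ``read_melting_csv``."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "ligand_conc_M": c.ligand_conc,
            "temperature_C": c.points[:, 0] - 273.15,
            "signal": c.points[:, 1],
        }))
    return pd.concat(frames, ignore_index=True).to_csv(index=False)
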