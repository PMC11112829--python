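"""Seeded generators for every input the prospecting pipeline consumes.

Each generator emulates one slice of a CDH discovery campaign with known
ground truth: protein families with planted class structure and sequence
features (signal peptide, heme ligands, YDY linker, Rossmann GxGxxG,
catalytic His), trees with planted sub-clades, coding sequences with
planted Type IIS recognition sites, linear assay traces, two-band UV-Vis
spectra and multi-step purification scenarios.  All randomness flows from
one explicit seed per artifact, and every generator returns a
:class:`ScenarioTruth` that serializes alongside the data.

Substitutions use a uniform exchange model — adequate for planting
identity-controlled family structure, but not a realistic evolutionary
model (no rate variation, no empirical exchangeabilities).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .biochem import AssayConfig, AssayMeasurement, PurificationStep, Spectrum
from .construct_design import (DEFAULT_ENZYMES, RestrictionEnzyme,
                               STANDARD_TABLE, scan_restriction_sites)
from .seqio import NucleotideRecord, ProteinRecord
from . import synthetic_reference as ref_layout
from .synthetic_reference import BACKGROUND, synthetic_reference_record


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class ScenarioTruth:
    """Ground truth serialized alongside every generated artifact."""

    kind: str
    data: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "data": _jsonify(self.data)},
                      fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioTruth":
        raw = json.loads(Path(path).read_text())
        return cls(raw["kind"], raw["data"])


# ---------------------------------------------------------------------------
# protein families

@dataclass(frozen=True)
class FeaturePlan:
    """Which sequence features a generated family member carries."""

    signal_peptide: bool = True
    rossmann: bool = True
    catalytic_his: bool = True
    heme_ligands: bool = True
    ydy: bool = True
    cterm_extension: bool = False


@dataclass
class FamilySpec:
    """Design of a planted protein family set.

    Members within a class hit ``within_identity`` pairwise and members of
    different classes ``between_identity`` (each ± 3 percentage points).
    ``class_root_divergence`` optionally overrides the per-class distance
    from the shared root (fraction of mutable positions) to design nested
    separation orders.  ``root="reference"`` grows everything out of the
    packaged synthetic reference so queries stay anchorable;
    ``root="random"`` uses a fresh background-composition ancestor of
    ``ancestor_length`` residues with the same relative feature layout.
    """

    n_classes: int = 1
    members_per_class: int = 5
    within_identity: float = 0.90
    between_identity: float = 0.60
    ancestor_length: int | None = None
    root: str = "reference"
    class_root_divergence: Sequence[float] | None = None
    feature_overrides: Mapping[str, FeaturePlan] = field(default_factory=dict)
    #: sample a fresh secretion leader per member (exercises the signal
    #: peptide heuristic); disable when very high within-class identity
    #: targets must be realized exactly (e.g. redundancy scenarios)
    vary_signal_peptides: bool = True
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.between_identity < self.within_identity < 1):
            raise ValueError("need 0 < between_identity < within_identity "
                             "< 1")


@dataclass
class FamilyLayout:
    """1-based feature coordinates shared by root and members (no indels)."""

    length: int
    sp_region: tuple[int, int]
    heme_met: int
    heme_his: int
    ydy: tuple[int, int]
    rossmann: tuple[int, int]
    catalytic_his: int


def _reference_layout() -> FamilyLayout:
    return FamilyLayout(
        length=ref_layout.REFERENCE_LENGTH,
        sp_region=(1, ref_layout.SP_END),
        heme_met=ref_layout.HEME_MET,
        heme_his=ref_layout.HEME_HIS,
        ydy=(ref_layout.YDY_START, ref_layout.YDY_START + 2),
        rossmann=(ref_layout.ROSSMANN_START, ref_layout.ROSSMANN_START + 5),
        catalytic_his=ref_layout.CATALYTIC_HIS,
    )


def _scaled_layout(length: int) -> FamilyLayout:
    if length < 120:
        raise ValueError("ancestor_length must be >= 120")
    scale = length / ref_layout.REFERENCE_LENGTH

    def pos(p: int) -> int:
        return max(1, min(length, round(p * scale)))

    ydy = max(pos(ref_layout.YDY_START), ref_layout.SP_END + 30)
    return FamilyLayout(
        length=length,
        sp_region=(1, ref_layout.SP_END),
        heme_met=max(25, pos(ref_layout.HEME_MET)),
        heme_his=max(40, pos(ref_layout.HEME_HIS)),
        ydy=(ydy, ydy + 2),
        rossmann=(ydy + 8, ydy + 13),
        catalytic_his=min(length - 5, pos(ref_layout.CATALYTIC_HIS)),
    )


def _protected_columns(layout: FamilyLayout) -> set[int]:
    """Columns mutations must not touch: planted features plus the windows
    the curation criteria search, so ablations alone decide a flag."""
    cols: set[int] = set()
    cols.update(range(layout.sp_region[0], layout.sp_region[1] + 1))
    cols.update((layout.heme_met, layout.heme_his, layout.catalytic_his))
    cols.update(range(max(1, layout.ydy[0] - 21),
                      min(layout.length, layout.ydy[1] + 21) + 1))
    cols.update(range(max(1, layout.rossmann[0] - 16),
                      min(layout.length, layout.rossmann[1] + 16) + 1))
    return cols


def _mutation_count(target_mismatch: int, mutable: int) -> int:
    """Per-sequence mutation count so two independently mutated copies of
    one ancestor show ``target_mismatch`` expected differences.

    Solves 2k - (20/19)·k²/M = target for k (collisions at positions both
    copies mutate still mismatch with probability 18/19).
    """
    if target_mismatch <= 0:
        return 0
    a = (20.0 / 19.0) / mutable
    disc = 4.0 - 4.0 * a * target_mismatch
    if disc <= 0:
        raise ValueError("identity target infeasible for this length")
    k = (2.0 - math.sqrt(disc)) / (2.0 * a)
    return int(round(k))


def _plant_layout(seq: list[str], layout: FamilyLayout) -> None:
    seq[layout.sp_region[0] - 1:layout.sp_region[1]] = list(
        ref_layout._SIGNAL_PEPTIDE[:layout.sp_region[1]])
    seq[layout.heme_met - 1] = "M"
    seq[layout.heme_his - 1] = "H"
    seq[layout.ydy[0] - 1:layout.ydy[1]] = list("YDY")
    seq[layout.rossmann[0] - 1:layout.rossmann[1]] = list(
        ref_layout._ROSSMANN)
    seq[layout.catalytic_his - 1] = "H"


def _scrub_windows(seq: list[str], layout: FamilyLayout) -> None:
    ref_layout._scrub(seq, "YDY", layout.ydy[0] - 1,
                      max(0, layout.ydy[0] - 26), layout.ydy[0] + 27)
    ref_layout._scrub(seq, "G.G..G", layout.rossmann[0] - 1,
                      max(0, layout.rossmann[0] - 21),
                      layout.rossmann[0] + 25)


_ABLATION_SP = (3, "DDEEDDEEDDEE")


def sample_signal_peptide(rng: np.random.Generator, length: int = 18) -> str:
    """A random secretion leader with n/h/c architecture.

    Methionine start, 1–2 basic residues (n-region), 9–12 strongly
    hydrophobic residues (h-region), and a small-residue c-region ending
    in Ala at the cleavage site.
    """
    n_len = int(rng.integers(1, 3))
    h_len = int(rng.integers(9, 13))
    n_region = "".join(rng.choice(list("KR"), size=n_len))
    h_region = "".join(rng.choice(list("LVIFA"), size=h_len,
                                  p=[0.35, 0.25, 0.15, 0.1, 0.15]))
    c_len = length - 1 - n_len - h_len
    c_region = ("STAGS" * 4)[:c_len - 1] + "A"
    return "M" + n_region + h_region + c_region


def _ablate(seq: list[str], layout: FamilyLayout,
            plan: FeaturePlan, rng: np.random.Generator
            ) -> tuple[list[int], str]:
    """Apply point ablations for every negative feature; returns 1-based
    changed positions and an appended C-terminal extension (if any)."""
    changed: list[int] = []

    def set_pos(p: int, aa: str) -> None:
        if seq[p - 1] != aa:
            seq[p - 1] = aa
            changed.append(p)

    if not plan.signal_peptide:
        start, repl = _ABLATION_SP
        for i, aa in enumerate(repl):
            set_pos(start + i, aa)
    if not plan.rossmann:
        lo = layout.rossmann[0]
        for off in (0, 2, 5):  # the three glycines of GxGxxG
            set_pos(lo + off, "A")
    if not plan.catalytic_his:
        set_pos(layout.catalytic_his, "A")
    if not plan.heme_ligands:
        set_pos(layout.heme_met, "A")
        set_pos(layout.heme_his, "A")
    if not plan.ydy:
        set_pos(layout.ydy[0] + 1, "A")
    extension = ""
    if plan.cterm_extension:
        letters, probs = _background_arrays()
        extension = "".join(rng.choice(letters, size=45, p=probs))
    return changed, extension


def _background_arrays():
    letters = np.array(list(BACKGROUND))
    probs = np.array([BACKGROUND[a] for a in BACKGROUND])
    return letters, probs / probs.sum()


def _mutate(seq: list[str], k: int, allowed: np.ndarray,
            rng: np.random.Generator) -> list[str]:
    out = list(seq)
    if k == 0:
        return out
    positions = rng.choice(allowed, size=k, replace=False)
    aas = list(BACKGROUND)
    for p in positions:
        current = out[p]
        choices = [a for a in aas if a != current]
        out[p] = choices[int(rng.integers(len(choices)))]
    return out


def generate_family(spec: FamilySpec
                    ) -> tuple[list[ProteinRecord], ScenarioTruth]:
    """Generate a planted multi-class protein family.

    Class ancestors diverge from a shared root, members diverge from their
    class ancestor, and feature-negative members differ from their
    (recorded) positive form at exactly the ablated positions.  Feature
    columns and the motif search windows are excluded from random
    mutation, so planted truth decides every curation flag.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.root == "reference":
        layout = _reference_layout()
        root = list(synthetic_reference_record().sequence)
    else:
        length = spec.ancestor_length or 400
        layout = _scaled_layout(length)
        letters, probs = _background_arrays()
        root = list(rng.choice(letters, size=length, p=probs))
        _plant_layout(root, layout)
        _scrub_windows(root, layout)

    protected = _protected_columns(layout)
    allowed = np.array(sorted(set(range(layout.length)) -
                              {p - 1 for p in protected}))
    mutable = len(allowed)
    L = layout.length

    k_member = _mutation_count(round(L * (1 - spec.within_identity)),
                               mutable)
    if spec.class_root_divergence is not None:
        if len(spec.class_root_divergence) != spec.n_classes:
            raise ValueError("class_root_divergence length must equal "
                             "n_classes")
        d_class = [round(f * mutable) for f in spec.class_root_divergence]
    else:
        total = _mutation_count(round(L * (1 - spec.between_identity)),
                                mutable)
        d = max(0, total - k_member)
        d_class = [d] * spec.n_classes
    if any(d > mutable for d in d_class) or 2 * k_member > mutable:
        raise ValueError("identity targets infeasible")

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    plans: dict[str, FeaturePlan] = {}
    ablated: dict[str, list[int]] = {}
    positives: dict[str, str] = {}
    for c in range(spec.n_classes):
        ancestor = _mutate(root, d_class[c], allowed, rng)
        for m in range(spec.members_per_class):
            acc = f"cls{c + 1}_m{m + 1:03d}"
            member = _mutate(ancestor, k_member, allowed, rng)
            plan = spec.feature_overrides.get(acc, FeaturePlan())
            if spec.vary_signal_peptides:
                # each member gets its own secretion leader so the
                # heuristic is exercised on varied n/h/c architectures
                sp_len = layout.sp_region[1] - layout.sp_region[0] + 1
                member[layout.sp_region[0] - 1:layout.sp_region[1]] = list(
                    sample_signal_peptide(rng, sp_len))
            positive = "".join(member)
            changed, extension = _ablate(member, layout, plan, rng)
            seq = "".join(member) + extension
            records.append(ProteinRecord(
                acc, seq, f"synthetic class {c + 1} member",
                class_label=str(c + 1)))
            labels[acc] = f"class_{c + 1}"
            plans[acc] = plan
            if changed or extension:
                ablated[acc] = changed
                positives[acc] = positive
    truth = ScenarioTruth("family", {
        "labels": labels,
        "layout": asdict(layout),
        "feature_plans": {a: asdict(p) for a, p in plans.items()},
        "ablated_positions": ablated,
        "positive_sequences": positives,
        "per_member_mutations": k_member,
        "class_root_mutations": d_class,
        "seed": spec.seed,
    })
    return records, truth


# ---------------------------------------------------------------------------
# trees

def generate_tree(
    clades: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    within_depth: float = 0.05,
    separation: float = 1.0,
    seed: int = 0,
) -> tuple[str, ScenarioTruth]:
    """Newick tree with planted sub-clades.

    Each clade becomes a random bifurcating subtree whose root-to-leaf
    depths stay below ``within_depth``, attached to the tree root by an
    edge of length ``separation``/2; cutting at any threshold between
    those two scales recovers the planted clades exactly.
    """
    if not isinstance(clades, Mapping):
        clades = {f"clade_{i + 1}": list(c) for i, c in enumerate(clades)}
    if len(clades) < 1 or any(not members for members in clades.values()):
        raise ValueError("need >= 1 non-empty clades")
    rng = np.random.default_rng(seed)

    def subtree(leaves: list[str], budget: float) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.uniform(0.1, 0.5) * budget:.6f}"
        k = int(rng.integers(1, len(leaves)))
        idx = rng.permutation(len(leaves))
        left = [leaves[i] for i in idx[:k]]
        right = [leaves[i] for i in idx[k:]]
        e1 = rng.uniform(0.1, 0.4) * budget
        e2 = rng.uniform(0.1, 0.4) * budget
        return (f"({subtree(left, budget - e1)}:{e1:.6f},"
                f"{subtree(right, budget - e2)}:{e2:.6f})")

    parts = [f"{subtree(list(m), within_depth)}:{separation / 2:.6f}"
             for m in clades.values()]
    newick = f"({','.join(parts)});"
    assignment = {leaf: label for label, members in clades.items()
                  for leaf in members}
    truth = ScenarioTruth("tree", {
        "assignment": assignment,
        "within_depth": within_depth,
        "separation": separation,
        "seed": seed,
    })
    return newick, truth


# ---------------------------------------------------------------------------
# coding sequences

_ENZYMES_BY_NAME = {e.name: e for e in DEFAULT_ENZYMES}
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in STANDARD_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


def _offset_realizable(protein: ProteinRecord, enz: RestrictionEnzyme,
                       offset: int) -> bool:
    n = len(protein.sequence) * 3
    if offset < 0 or offset + len(enz.recognition) > n:
        return False
    for ci in range(offset // 3, (offset + len(enz.recognition) - 1) // 3 + 1):
        aa = protein.sequence[ci]
        wanted = {p - ci * 3: b
                  for p, b in enumerate(enz.recognition, start=offset)
                  if ci * 3 <= p < ci * 3 + 3}
        if not any(all(c[o] == b for o, b in wanted.items())
                   for c in _CODONS_BY_AA.get(aa, [])):
            return False
    return True


def plantable_offsets(
    protein: ProteinRecord,
    enzyme: str | RestrictionEnzyme,
) -> list[int]:
    """All nt offsets where the enzyme's site can be planted synonymously."""
    enz = _ENZYMES_BY_NAME[enzyme] if isinstance(enzyme, str) else enzyme
    n = len(protein.sequence) * 3
    return [o for o in range(n - len(enz.recognition) + 1)
            if _offset_realizable(protein, enz, o)]


def generate_cds(
    protein: ProteinRecord,
    planted_sites: Sequence[tuple[str | RestrictionEnzyme, int]] = (),
    seed: int = 0,
    include_stop: bool = True,
) -> tuple[NucleotideRecord, ScenarioTruth]:
    """Reverse-translate a protein, planting recognition sites.

    Each planted site ``(enzyme, nt_offset)`` is embedded by constraining
    the overlapped codons to synonymous codons matching the recognition
    sequence at that offset; an offset where no synonymous assignment
    exists raises.  Chance sites arising from random codon choice are
    recorded in the truth alongside the planted ones.
    """
    rng = np.random.default_rng(seed)
    codons: list[str] = []
    for aa in protein.sequence:
        options = _CODONS_BY_AA.get(aa)
        if not options:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[int(rng.integers(len(options)))])

    constraints: dict[int, str] = {}
    planted = []
    for enzyme, offset in planted_sites:
        enz = (_ENZYMES_BY_NAME[enzyme] if isinstance(enzyme, str)
               else enzyme)
        target = enz.recognition
        for i, base in enumerate(target):
            pos = offset + i
            if constraints.get(pos, base) != base:
                raise ValueError(f"planted sites conflict at nt {pos}")
            constraints[pos] = base
        planted.append({"enzyme": enz.name, "offset": offset})
    for ci in sorted({p // 3 for p in constraints}):
        aa = protein.sequence[ci]
        wanted = {p - ci * 3: b for p, b in constraints.items()
                  if ci * 3 <= p < ci * 3 + 3}
        options = [c for c in _CODONS_BY_AA[aa]
                   if all(c[o] == b for o, b in wanted.items())]
        if not options:
            raise ValueError(
                f"site unrealizable: codon {ci} ({aa}) cannot match "
                f"{wanted}")
        if codons[ci] not in options:
            codons[ci] = options[0]

    seq = "".join(codons) + ("TAA" if include_stop else "")
    record = NucleotideRecord(protein.accession + "_cds", seq,
                              f"reverse-translated from {protein.accession}")
    sites = scan_restriction_sites(record)
    truth = ScenarioTruth("cds", {
        "protein": protein.sequence,
        "planted_sites": planted,
        "all_sites": [{"enzyme": s.enzyme, "start": s.start,
                       "strand": s.strand} for s in sites],
        "seed": seed,
        "include_stop": include_stop,
    })
    return record, truth


# ---------------------------------------------------------------------------
# assays, spectra, purification

def simulate_assay(
    true_activity: float,
    cfg: AssayConfig,
    noise_sd: float = 0.0,
    n_points: int = 19,
    duration_min: float = 3.0,
    seed: int = 0,
    dilution: float = 1.0,
    sample_fraction: float = 1.0,
    a0: float = 0.1,
) -> tuple[AssayMeasurement, ScenarioTruth]:
    """Linear absorbance trace for a known volumetric activity (U mL⁻¹).

    Inverts the activity arithmetic — slope = activity·ε·path·f/dilution —
    and adds Gaussian absorbance noise.  The trace is rendered with a
    positive slope (signal magnitude convention).
    """
    if true_activity < 0:
        raise ValueError("true_activity must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    slope = (true_activity * cfg.extinction_mM * cfg.path_cm
             * sample_fraction / dilution)
    t = np.linspace(0.0, duration_min, n_points)
    a = a0 + slope * t + rng.normal(0.0, noise_sd, size=n_points)
    m = AssayMeasurement(time_min=t, absorbance=a, dilution=dilution,
                         sample_fraction=sample_fraction)
    truth = ScenarioTruth("assay", {
        "true_activity_U_per_ml": true_activity,
        "true_slope_au_per_min": slope,
        "noise_sd": noise_sd, "seed": seed,
    })
    return m, truth


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


#: band model constants (centers nm / widths nm / ε in mM⁻¹cm⁻¹)
SPECTRUM_MODEL = {
    "protein": (280.0, 14.0, 100.185),
    "soret_ox": (420.0, 11.0, 100.0),
    "soret_red": (429.0, 11.0, 110.0),
    "flavin": (450.0, 28.0, 11.3),
    "alpha": (562.0, 5.0, 25.0),
    "beta": (533.0, 7.0, 15.0),
}


def simulate_spectrum(
    protein_conc_uM: float = 5.0,
    occupancy: float = 1.0,
    heme: float = 1.0,
    state: str = "oxidized",
    seed: int = 0,
    noise_sd: float = 0.0,
    grid_nm: tuple[float, float, float] = (250.0, 700.0, 1.0),
) -> tuple[Spectrum, ScenarioTruth]:
    """Sum-of-Gaussian flavocytochrome UV-Vis spectrum.

    Protein band at 280 nm, heme Soret at 420 nm (oxidized) shifting to
    429 nm (reduced) plus α/β bands in the reduced state, and a flavin
    band at 450 nm scaled by FAD occupancy (oxidized state only).
    ``heme`` scales the heme bands (0 for an isolated DH domain).
    """
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi, step = grid_nm
    x = np.arange(lo, hi + step / 2, step)
    p_mM = protein_conc_uM / 1000.0
    c, w, e = SPECTRUM_MODEL["protein"]
    a = p_mM * e * _gaussian(x, c, w)
    soret_center = None
    if heme > 0:
        key = "soret_ox" if state == "oxidized" else "soret_red"
        c, w, e = SPECTRUM_MODEL[key]
        soret_center = c
        a = a + heme * p_mM * e * _gaussian(x, c, w)
        if state == "reduced":
            for band in ("alpha", "beta"):
                c, w, e = SPECTRUM_MODEL[band]
                a = a + heme * p_mM * e * _gaussian(x, c, w)
    if state == "oxidized" and occupancy > 0:
        c, w, e = SPECTRUM_MODEL["flavin"]
        a = a + occupancy * p_mM * e * _gaussian(x, c, w)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=len(x))
    spectrum = Spectrum(x, a, state)
    truth = ScenarioTruth("spectrum", {
        "protein_conc_uM": protein_conc_uM,
        "occupancy": occupancy,
        "heme": heme,
        "state": state,
        "soret_center_nm": soret_center,
        "noise_sd": noise_sd,
        "seed": seed,
    })
    return spectrum, truth


def simulate_purification(
    step_recoveries: Sequence[float],
    purity_factors: Sequence[float],
    reference: Mapping[str, object] | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    bdl: set[tuple[int, str]] = frozenset(),
) -> tuple[list[PurificationStep], ScenarioTruth]:
    """Multi-step purification scenario with closed-form truth.

    ``step_recoveries`` are per-step activity recoveries in (0, 1];
    ``purity_factors`` the per-step specific-activity gains (relative to
    the starting material, non-decreasing).  ``bdl`` marks
    ``(step_index, assay)`` pairs (0 = first step after the reference)
    whose measured activity falls below the detection limit.
    """
    if len(step_recoveries) != len(purity_factors):
        raise ValueError("recoveries and purities must have equal length")
    if any(not 0 < r <= 1 for r in step_recoveries):
        raise ValueError("recoveries must be in (0, 1]")
    if any(nxt < prev for prev, nxt in zip(purity_factors,
                                           purity_factors[1:])):
        raise ValueError("purity factors must be non-decreasing")
    reference = dict(reference or {})
    ref_volume = float(reference.get("volume_ml", 1000.0))
    ref_protein = float(reference.get("protein_mg", 500.0))
    ref_activities = dict(reference.get(
        "activities", {"dcip": 400.0, "cytc": 20.0}))
    rng = np.random.default_rng(seed)
    primary = next(iter(ref_activities))
    ref_spec = ref_activities[primary] / ref_protein

    steps = [PurificationStep(
        "supernatant", ref_volume, ref_protein / ref_volume,
        {a: float(v) for a, v in ref_activities.items()})]
    truth_rows = []
    cumulative = 1.0
    for i, (rec, pf) in enumerate(zip(step_recoveries, purity_factors)):
        cumulative *= rec
        noise = (rng.lognormal(0.0, noise_cv)
                 if noise_cv > 0 else 1.0)
        activities: dict[str, float | None] = {}
        for a, ref_act in ref_activities.items():
            activities[a] = (None if (i, a) in bdl
                             else float(ref_act) * cumulative * noise)
        act_primary = float(ref_activities[primary]) * cumulative * noise
        spec = ref_spec * pf
        protein = act_primary / spec
        volume = ref_volume / (4.0 ** (i + 1))
        steps.append(PurificationStep(
            f"step_{i + 1}", volume, protein / volume, activities))
        truth_rows.append({
            "label": f"step_{i + 1}",
            "total_protein_mg": protein,
            "yield_pct": {a: (None if (i, a) in bdl
                              else 100.0 * activities[a] / ref_activities[a])
                          for a in ref_activities},
            "specific_activity": {a: (None if (i, a) in bdl
                                      else activities[a] / protein)
                                  for a in ref_activities},
            "purification_factor_primary": spec / ref_spec,
        })
    truth = ScenarioTruth("purification", {
        "primary_assay": primary,
        "reference": {"volume_ml": ref_volume, "protein_mg": ref_protein,
                      "activities": ref_activities},
        "steps": truth_rows,
        "seed": seed,
        "noise_cv": noise_cv,
    })
    return steps, truth
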