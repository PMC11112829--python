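"""Reference-anchored curation of putative class III CDH sequences.

A two-domain cellobiose dehydrogenase carries, from N- to C-terminus: a
secretion signal peptide, a cytochrome domain binding heme *b* through a
Met/His ligand pair, a flexible linker, and an FAD-dependent dehydrogenase
domain whose Rossmann fold opens with a glycine-rich GxGxxG motif preceded
by a conserved YDY tripeptide and whose active site contains a catalytic
histidine.  This module operationalises those five features as pass/fail
criteria by aligning each query globally to an annotated, biochemically
characterised reference and reading the query residues at the mapped
positions.  It also provides redundancy reduction, alignment-column
trimming, reference-column sequence logos, domain splitting at the linker,
distance-threshold clade extraction from a phylogenetic tree, and the final
per-clade candidate selection.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np

from . import align
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

Flag = Literal["pass", "fail", "unknown"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte–Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


# ---------------------------------------------------------------------------
# reference annotation

@dataclass(frozen=True)
class ReferenceAnnotation:
    """A characterised reference sequence with 1-based feature coordinates.

    The default coordinates follow the numbering of the class I CDH used as
    the anchoring standard: heme ligands Met65 and His163 in the cytochrome
    domain, catalytic His689 in the dehydrogenase domain, and the YDY
    tripeptide sitting eight residues after the domain split point at the
    start of the Rossmann fold.
    """

    reference: ProteinRecord
    heme_met_pos: int = 65
    heme_his_pos: int = 163
    catalytic_his_pos: int = 689
    cyt_region: tuple[int, int] = (19, 215)
    dh_region: tuple[int, int] = (230, 770)
    rossmann_pattern: str = "GxGxxG"
    linker_anchor_motif: str = "YDY"
    linker_offset: int = 8
    rossmann_window: int = 15

    def __post_init__(self) -> None:
        seq = self.reference.sequence
        for pos, expect, what in (
            (self.heme_met_pos, "M", "heme Met"),
            (self.heme_his_pos, "H", "heme His"),
            (self.catalytic_his_pos, "H", "catalytic His"),
        ):
            if seq[pos - 1] != expect:
                raise ValueError(
                    f"reference residue at {what} position {pos} is "
                    f"{seq[pos - 1]!r}, expected {expect!r}")
        if not self.cyt_region[0] <= self.cyt_region[1] < self.dh_region[0]:
            raise ValueError("regions must be ordered Cyt < DH and disjoint")

    @property
    def rossmann_regex(self) -> re.Pattern:
        pat = self.rossmann_pattern.replace("x", ".")
        return re.compile(pat)

    @property
    def rossmann_start(self) -> int:
        """1-based start of the first Rossmann motif at/after the DH start."""
        m = self.rossmann_regex.search(
            self.reference.sequence, self.dh_region[0] - 1)
        if m is None:
            raise ValueError("reference lacks the Rossmann motif in its DH "
                             "region")
        return m.start() + 1

    @property
    def ydy_start(self) -> int:
        """1-based start of the YDY linker anchor nearest the DH start."""
        idx = self.reference.sequence.find(
            self.linker_anchor_motif, self.dh_region[0] - 1)
        if idx < 0:
            raise ValueError("reference lacks the YDY anchor")
        return idx + 1


def default_reference() -> ReferenceAnnotation:
    """The packaged (synthetic) annotated reference."""
    from .synthetic_reference import synthetic_reference_annotation
    return synthetic_reference_annotation()


# ---------------------------------------------------------------------------
# anchoring

@dataclass
class AnchorResult:
    """Outcome of globally aligning a query to the reference."""

    accession: str
    anchorable: bool
    identity: float
    column_map: dict[int, int] = field(default_factory=dict)
    #: 1-based query positions for each annotated landmark; None when gapped
    landmarks: dict[str, int | None] = field(default_factory=dict)


def anchor_to_reference(
    query: ProteinRecord,
    ref: ReferenceAnnotation,
    identity_floor: float = 0.20,
    min_query_length: int = 100,
) -> AnchorResult:
    """Map annotated reference positions onto a query via global alignment.

    Alignments below ``identity_floor`` percent identity mark the query
    unanchorable; criteria that rely on the map then report ``unknown``.
    The default floor (20 %) sits above the ~16 % identity that globally
    aligned unrelated proteins reach by chance under affine gap scoring.
    """
    if len(query) < min_query_length:
        raise ValueError(
            f"{query.accession}: query shorter than {min_query_length} "
            "residues cannot be anchored")
    alignment = align.global_alignment(ref.reference.sequence, query.sequence)
    identity = align.alignment_identity(alignment)
    if identity < identity_floor:
        return AnchorResult(query.accession, False, identity)
    cmap = align.column_map(alignment)
    landmarks = {
        "heme_met": cmap.get(ref.heme_met_pos),
        "heme_his": cmap.get(ref.heme_his_pos),
        "catalytic_his": cmap.get(ref.catalytic_his_pos),
        "rossmann_start": cmap.get(ref.rossmann_start),
        "ydy_start": cmap.get(ref.ydy_start),
        "dh_start": cmap.get(ref.dh_region[0]),
    }
    return AnchorResult(query.accession, True, identity, cmap, landmarks)


# ---------------------------------------------------------------------------
# signal peptide heuristic

@dataclass
class SignalPeptideCall:
    passed: bool
    score: float
    cleavage_pos: int | None
    reason: str = ""
    source: str = "heuristic"


def predict_signal_peptide(
    query: ProteinRecord | str,
    min_hydropathy: float = 1.8,
    h_window: int = 7,
    latest_h_start: int = 12,
    search_limit: int = 30,
) -> SignalPeptideCall:
    """Heuristic secretion-signal check on the N-terminus.

    Requires, within the first ``search_limit`` residues: a non-negatively
    charged n-region, followed by a hydrophobic h-region (a window of
    ``h_window`` residues starting no later than position ``latest_h_start``
    with mean Kyte–Doolittle hydropathy >= ``min_hydropathy``), followed by
    a small-residue cleavage context (A/G/S within 12 residues of the
    h-region end).  This emulates the n/h/c architecture that dedicated
    predictors model statistically; tabular output of such a predictor can
    be supplied to :func:`curate_dataset` instead and overrides this check.
    """
    seq = query.sequence if isinstance(query, ProteinRecord) else query
    if len(seq) < 25:
        return SignalPeptideCall(False, 0.0, None, "too short")
    head = seq[:search_limit]
    kd = [KYTE_DOOLITTLE.get(c, 0.0) for c in head]
    best_score, best_start = -math.inf, None
    for s in range(1, min(latest_h_start, len(head) - h_window) + 1):
        mean = sum(kd[s:s + h_window]) / h_window
        if mean > best_score:
            best_score, best_start = mean, s
    if best_start is None or best_score < min_hydropathy:
        return SignalPeptideCall(False, best_score if best_start else 0.0,
                                 None, "no hydrophobic h-region")
    n_region = head[:best_start]
    charge = sum(c in "KR" for c in n_region) - sum(c in "DE" for c in n_region)
    if charge < 0:
        return SignalPeptideCall(False, best_score, None,
                                 "negatively charged n-region")
    # extend the h-region while it stays hydrophobic
    end = best_start + h_window
    while end < len(head) and kd[end] > 0:
        end += 1
    c_region = seq[end:min(end + 12, len(seq))]
    small = [i for i, c in enumerate(c_region) if c in "AGS"]
    if not small:
        return SignalPeptideCall(False, best_score, None,
                                 "no small-residue cleavage context")
    cleavage = end + small[-1] + 1
    return SignalPeptideCall(True, best_score, cleavage)


def read_signalp_table(path: str | Path) -> dict[str, bool]:
    """Adapter for external signal-peptide predictor output.

    Accepts the whitespace/tab-delimited short format with columns
    ``ID  Prediction  ...`` where the prediction is ``OTHER`` for no signal
    peptide and anything else (e.g. ``SP(Sec/SPI)``) for a positive call.
    Lines starting with ``#`` are ignored.
    """
    calls: dict[str, bool] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        calls[fields[0]] = fields[1].upper() != "OTHER"
    return calls


# ---------------------------------------------------------------------------
# the five criteria

CRITERIA = ("has_signal_peptide", "has_rossmann", "has_catalytic_his",
            "has_cyt_domain", "has_heme_ligands")


@dataclass
class CurationReport:
    """Per-sequence outcome of the five functional-candidate criteria."""

    accession: str
    flags: dict[str, Flag]
    verdict: Literal["kept", "excluded"]
    reasons: list[str] = field(default_factory=list)
    landmarks: dict[str, int | None] = field(default_factory=dict)
    anchor_identity: float = 0.0


def _query_window(cmap: Mapping[int, int], lo: int, hi: int) -> tuple[int, int] | None:
    """Query interval (1-based, inclusive) covered by reference columns
    lo..hi; None if no column in the range maps."""
    mapped = [cmap[p] for p in range(lo, hi + 1) if p in cmap]
    if not mapped:
        return None
    return min(mapped), max(mapped)


def evaluate_record(
    query: ProteinRecord,
    ref: ReferenceAnnotation,
    sp_call: bool | None = None,
    cyt_coverage_floor: float = 0.6,
    identity_floor: float = 0.20,
) -> CurationReport:
    """Apply the five criteria to one query.

    ``sp_call`` overrides the built-in signal-peptide heuristic (use an
    external predictor's verdict).  An unanchorable query leaves every
    alignment-based flag ``unknown`` and is excluded.
    """
    seq = query.sequence
    if sp_call is None:
        sp = predict_signal_peptide(query)
        sp_flag: Flag = "pass" if sp.passed else "fail"
    else:
        sp_flag = "pass" if sp_call else "fail"

    anchor = anchor_to_reference(query, ref, identity_floor=identity_floor)
    flags: dict[str, Flag] = {"has_signal_peptide": sp_flag}
    if not anchor.anchorable:
        for crit in CRITERIA[1:]:
            flags[crit] = "unknown"
        return CurationReport(query.accession, flags, "excluded",
                              ["unanchorable"], {}, anchor.identity)

    cmap = anchor.column_map
    lm = anchor.landmarks

    def residue_is(qpos: int | None, letter: str) -> Flag:
        if qpos is None:
            return "fail"
        return "pass" if seq[qpos - 1] == letter else "fail"

    flags["has_catalytic_his"] = residue_is(lm["catalytic_his"], "H")
    met_ok = residue_is(lm["heme_met"], "M")
    his_ok = residue_is(lm["heme_his"], "H")
    flags["has_heme_ligands"] = (
        "pass" if met_ok == his_ok == "pass" else "fail")

    # Rossmann GxGxxG within the query region aligned to the reference
    # motif neighbourhood (+- rossmann_window columns)
    w = ref.rossmann_window
    window = _query_window(cmap, ref.rossmann_start - w,
                           ref.rossmann_start + 5 + w)
    if window is None:
        flags["has_rossmann"] = "fail"
    else:
        qlo, qhi = window
        hit = ref.rossmann_regex.search(seq, qlo - 1, qhi)
        flags["has_rossmann"] = "pass" if hit else "fail"

    # N-terminal Cyt domain: enough of the reference Cyt region must map,
    # and it must sit before the mapped DH start
    lo, hi = ref.cyt_region
    mapped = [cmap[p] for p in range(lo, hi + 1) if p in cmap]
    coverage = len(mapped) / (hi - lo + 1)
    dh_start = lm["dh_start"] or (max(cmap.values()) + 1)
    n_terminal = bool(mapped) and max(mapped) < dh_start
    flags["has_cyt_domain"] = (
        "pass" if coverage >= cyt_coverage_floor and n_terminal else "fail")

    reasons = [c for c in CRITERIA if flags[c] != "pass"]
    verdict = "kept" if not reasons else "excluded"
    return CurationReport(query.accession, flags, verdict, reasons,
                          lm, anchor.identity)


def curate_dataset(
    records: Sequence[ProteinRecord],
    ref: ReferenceAnnotation,
    sp_calls: Mapping[str, bool] | None = None,
    **kwargs,
) -> tuple[list[ProteinRecord], list[CurationReport], dict[str, int]]:
    """Apply :func:`evaluate_record` to a dataset.

    Returns the kept subset, every report, and per-criterion exclusion
    tallies (a record failing several criteria counts once per criterion).
    """
    kept: list[ProteinRecord] = []
    reports: list[CurationReport] = []
    tallies = {c: 0 for c in CRITERIA}
    tallies["unanchorable"] = 0
    for rec in records:
        call = sp_calls.get(rec.accession) if sp_calls else None
        report = evaluate_record(rec, ref, sp_call=call, **kwargs)
        reports.append(report)
        if report.verdict == "kept":
            kept.append(rec)
        else:
            for reason in report.reasons:
                tallies[reason] = tallies.get(reason, 0) + 1
    return kept, reports, tallies


# ---------------------------------------------------------------------------
# redundancy reduction

@dataclass
class RedundancyCluster:
    representative: ProteinRecord
    members: list[str]


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.99,
) -> list[RedundancyCluster]:
    """Greedy first-fit clustering at a global-identity threshold.

    A record joins the first existing representative whose pairwise global
    alignment identity is >= the threshold, otherwise it founds a new
    cluster; representatives are returned in founding order.  This mirrors
    the deterministic behaviour of alignment-viewer redundancy removal at
    the customary >= 99 % setting.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    clusters: list[RedundancyCluster] = []
    for rec in records:
        for cluster in clusters:
            ident = align.global_identity(
                cluster.representative.sequence, rec.sequence)
            if ident >= identity_threshold:
                cluster.members.append(rec.accession)
                break
        else:
            clusters.append(RedundancyCluster(rec, [rec.accession]))
    return clusters


# ---------------------------------------------------------------------------
# alignment trimming and logos

def trim_alignment_columns(
    alignment: Sequence[str],
    max_gap_fraction: float = 0.9,
) -> tuple[list[str], list[int]]:
    """Drop columns whose gap fraction is >= ``max_gap_fraction``.

    The customary pre-tree trimming step (>= 90 % gap columns removed).
    Returns the trimmed rows and the 0-based indices of removed columns.
    """
    lengths = {len(row) for row in alignment}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: rows differ in length")
    if not alignment:
        return [], []
    n = len(alignment)
    ncol = lengths.pop()
    removed = [
        j for j in range(ncol)
        if sum(row[j] == "-" for row in alignment) / n >= max_gap_fraction
    ]
    removed_set = set(removed)
    trimmed = [
        "".join(c for j, c in enumerate(row) if j not in removed_set)
        for row in alignment
    ]
    return trimmed, removed


@dataclass
class LogoMatrix:
    """Per-reference-column residue frequencies and information content."""

    region_label: str
    positions: list[int]              # 1-based reference positions
    frequencies: np.ndarray           # (n_columns, 20)
    information: np.ndarray           # bits, 0 .. log2(20)
    coverage: np.ndarray              # fraction of records mapping per column
    alphabet: str = AMINO_ACIDS

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tinformation\tcoverage\t"
                     + "\t".join(self.alphabet) + "\n")
            for i, pos in enumerate(self.positions):
                freqs = "\t".join(f"{f:.6g}" for f in self.frequencies[i])
                fh.write(f"{pos}\t{self.information[i]:.6g}\t"
                         f"{self.coverage[i]:.6g}\t{freqs}\n")


def build_logo(
    records: Sequence[ProteinRecord],
    ref: ReferenceAnnotation,
    region: tuple[int, int],
    label: str | None = None,
) -> LogoMatrix:
    """Residue frequencies on reference columns via star alignment.

    Each record is anchored to the reference independently; column ``p`` of
    the logo collects the query residues aligned to reference position
    ``p``.  Information content is R = log2(20) - H(column) over the
    non-gap characters (no small-sample correction).
    """
    lo, hi = region
    if not 1 <= lo <= hi <= len(ref.reference):
        raise ValueError("region outside reference bounds")
    anchors = [anchor_to_reference(r, ref) for r in records]
    anchored = [(r, a) for r, a in zip(records, anchors) if a.anchorable]
    if len(anchored) < 2:
        raise ValueError("need >= 2 anchorable records for a logo")
    if len(anchored) < 0.5 * len(records):
        warnings.warn(f"fewer than half the records anchor to the reference "
                      f"({len(anchored)}/{len(records)})")
    positions = list(range(lo, hi + 1))
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((len(positions), 20))
    cover = np.zeros(len(positions))
    for rec, anchor in anchored:
        for i, p in enumerate(positions):
            qp = anchor.column_map.get(p)
            if qp is None:
                continue
            cover[i] += 1
            aa = rec.sequence[qp - 1]
            if aa in idx:
                counts[i, idx[aa]] += 1
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    info = np.zeros(len(positions))
    for i, tot in enumerate(totals):
        if tot > 0:
            freqs[i] = counts[i] / tot
            nz = freqs[i][freqs[i] > 0]
            info[i] = math.log2(20) + float(np.sum(nz * np.log2(nz)))
    return LogoMatrix(label or f"{lo}-{hi}", positions, freqs, info,
                      cover / len(anchored))


# ---------------------------------------------------------------------------
# domain splitting

@dataclass
class DomainSplit:
    """1-based, inclusive segment boundaries of a two-domain CDH query."""

    accession: str
    sp: tuple[int, int] | None
    cyt: tuple[int, int]
    linker: tuple[int, int] | None
    dh: tuple[int, int]
    cterm: tuple[int, int] | None
    dh_start: int
    fallback: bool = False

    def segment(self, seq: str, which: str) -> str:
        iv = getattr(self, which)
        return "" if iv is None else seq[iv[0] - 1:iv[1]]


def split_domains(
    query: ProteinRecord,
    ref: ReferenceAnnotation,
    sp_end: int | None = None,
    ydy_search_halfwidth: int = 20,
) -> DomainSplit:
    """Split a query into SP / Cyt / linker / DH / C-terminal extension.

    The DH domain starts ``linker_offset`` (8) residues before the YDY
    tripeptide found near the query region aligned to the reference YDY
    anchor; when no YDY is present there, the split falls back to the query
    position aligned to the reference DH start and the result is flagged.
    """
    anchor = anchor_to_reference(query, ref)
    seq = query.sequence
    if sp_end is None:
        call = predict_signal_peptide(query)
        sp_end = call.cleavage_pos if call.passed else 0
    ydy_q = None
    if anchor.anchorable and anchor.landmarks["ydy_start"] is not None:
        center = anchor.landmarks["ydy_start"]
        lo = max(0, center - 1 - ydy_search_halfwidth)
        hi = min(len(seq), center - 1 + ydy_search_halfwidth + 3)
        found = seq.find(ref.linker_anchor_motif, lo, hi)
        if found >= 0:
            ydy_q = found + 1
    fallback = False
    if ydy_q is not None:
        dh_start = ydy_q - ref.linker_offset
    else:
        if not anchor.anchorable or anchor.landmarks["dh_start"] is None:
            raise ValueError(
                f"{query.accession}: no YDY anchor and not anchorable")
        dh_start = anchor.landmarks["dh_start"]
        fallback = True
    if dh_start < sp_end + 2:
        raise ValueError(f"{query.accession}: DH start inside signal peptide")

    # Cyt ends where the mapped reference Cyt region ends; the remainder up
    # to the DH start is linker
    cyt_cols = [anchor.column_map[p]
                for p in range(ref.cyt_region[0], ref.cyt_region[1] + 1)
                if p in anchor.column_map] if anchor.anchorable else []
    cyt_end = min(max(cyt_cols), dh_start - 1) if cyt_cols else dh_start - 1
    dh_end_col = (anchor.column_map.get(ref.dh_region[1])
                  if anchor.anchorable else None)
    dh_end = dh_end_col if dh_end_col is not None else len(seq)
    return DomainSplit(
        accession=query.accession,
        sp=(1, sp_end) if sp_end else None,
        cyt=(sp_end + 1, cyt_end),
        linker=(cyt_end + 1, dh_start - 1) if cyt_end + 1 <= dh_start - 1 else None,
        dh=(dh_start, dh_end),
        cterm=(dh_end + 1, len(seq)) if dh_end < len(seq) else None,
        dh_start=dh_start,
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# clades and candidate selection

@dataclass
class CladeAssignment:
    """Leaf-to-sub-clade mapping from a distance-threshold tree cut."""

    assignment: dict[str, str]
    threshold: float
    outgroups: frozenset[str]

    @property
    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for leaf, clade in self.assignment.items():
            out.setdefault(clade, []).append(leaf)
        return {c: sorted(m) for c, m in sorted(out.items())}

    @property
    def n_clades(self) -> int:
        return len(set(self.assignment.values()))


def clades_from_tree(
    tree: str | Path | dendropy.Tree,
    threshold: float = 0.4,
    outgroups: set[str] | frozenset[str] = frozenset(),
) -> CladeAssignment:
    """Cut a tree into sub-clades at a cumulative-distance threshold.

    After pruning outgroup leaves, every edge whose root-to-node path
    distance first exceeds ``threshold`` is cut; the leaves of each severed
    subtree form one sub-clade, and leaves whose path never exceeds the
    threshold form a final residual clade.  Clades are numbered
    deterministically by their alphabetically smallest leaf.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if "(" not in text and Path(text).exists():
            t = dendropy.Tree.get(path=text, schema="newick",
                                  preserve_underscores=True)
        else:
            t = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    outgroups = frozenset(outgroups)
    if outgroups:
        keep = [leaf.taxon for leaf in t.leaf_node_iter()
                if leaf.taxon.label not in outgroups]
        t.retain_taxa(keep)

    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")

    groups: list[list[str]] = []

    def walk(node, depth: float) -> None:
        for child in node.child_nodes():
            d = depth + (child.edge.length or 0.0)
            if d > threshold:
                groups.append(sorted(
                    leaf.taxon.label for leaf in child.leaf_iter()))
            else:
                if child.is_leaf():
                    residual.append(child.taxon.label)
                else:
                    walk(child, d)

    residual: list[str] = []
    if t.seed_node.is_leaf():
        residual.append(t.seed_node.taxon.label)
    else:
        walk(t.seed_node, 0.0)
    if residual:
        groups.append(sorted(residual))

    groups.sort(key=lambda g: g[0])
    width = max(2, len(str(len(groups))))
    assignment = {
        leaf: f"clade_{i + 1:0{width}d}"
        for i, group in enumerate(groups) for leaf in group
    }
    return CladeAssignment(assignment, threshold, outgroups)


def select_candidates(
    assignment: CladeAssignment,
    records: Sequence[ProteinRecord],
    per_clade: int = 1,
    priority_lifestyle: str = "plant-associated",
) -> list[ProteinRecord]:
    """Pick expression candidates spread across sub-clades.

    Per sub-clade, ``per_clade`` records are chosen, preferring records
    whose lifestyle matches ``priority_lifestyle`` (organism ecology is a
    proxy for biological relevance of the enzyme), with ties broken by
    accession order.  Deterministic by construction.
    """
    by_accession = {r.accession: r for r in records}
    selected: list[ProteinRecord] = []
    for clade, members in assignment.clades.items():
        present = [by_accession[m] for m in members if m in by_accession]
        if not present:
            warnings.warn(f"{clade}: no records for its leaves, skipped")
            continue
        present.sort(key=lambda r: (r.lifestyle != priority_lifestyle,
                                    r.accession))
        selected.extend(present[:per_clade])
    return selected
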