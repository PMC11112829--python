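"""Sequence similarity networks and alignment-score threshold sweeps.

Nodes are protein records; an edge carries an expectation-style alignment
score (AS) derived from the optimal local alignment of the pair — lower AS
means stronger similarity.  Building the network once at a loose threshold
(1e-30 by default, with sequences pre-filtered to 150–1100 residues) and
then *sweeping* a series of decreasing cut-offs turns cluster analysis into
pure graph filtering: protein families fall out of the giant component one
by one as their bridging edges are pruned, and a family's "separation
cut-off" is the first cut-off at which it occupies components of its own.

The AS here is computed from a Smith–Waterman score under BLOSUM62 with
affine gaps (11/1), converted to bits with standard gapped Karlin–Altschul
parameters and to an expectation AS = m·n·2^(-bits).  Absolute AS values
from other tools will differ; cluster-separation behaviour, not absolute
counts, is the supported contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from . import align
from .align import ScoringParams
from .seqio import ProteinRecord

#: smallest representable AS; exact values live in ``log10_score``
_AS_FLOOR = 1e-300


class ScoreError(ValueError):
    """Pair cannot be scored (e.g. only unknown residues)."""


@dataclass(frozen=True)
class SimilarityEdge:
    """One scored unordered pair.  ``score`` is the AS (floored at 1e-300
    to stay positive); ``log10_score`` is exact and is what comparisons
    against cut-offs use."""

    a: str
    b: str
    score: float
    percent_identity: float
    log10_score: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-edges are not allowed")


@dataclass
class NetworkParams:
    scoring: ScoringParams = field(default_factory=ScoringParams)
    #: multiplies m·n in the expectation; models an effective database size
    search_space_scale: float = 1.0


def _raw_to_log10_as(raw: float, m: int, n: int, p: NetworkParams) -> float:
    bits = (p.scoring.lam * raw - math.log(p.scoring.k)) / math.log(2.0)
    return math.log10(m * n * p.search_space_scale) - bits * math.log10(2.0)


def score_pair(
    x: ProteinRecord,
    y: ProteinRecord,
    params: NetworkParams | None = None,
) -> SimilarityEdge:
    """Score one unordered pair of sequences.

    Computes the optimal local alignment, converts the raw score to bits
    and to AS = m·n·2^(-bits).  The substitution matrix is symmetric, so a
    single alignment covers both orientations.
    """
    params = params or NetworkParams()
    for rec in (x, y):
        if not rec.sequence or set(rec.sequence) == {"X"}:
            raise ScoreError(f"{rec.accession}: sequence has no scorable "
                             "residues")
    alignment = align.local_alignment(x.sequence, y.sequence, params.scoring)
    raw = float(alignment.score)
    log10_as = _raw_to_log10_as(raw, len(x), len(y), params)
    return SimilarityEdge(
        a=x.accession, b=y.accession,
        score=max(10.0 ** log10_as if log10_as > -300 else 0.0, _AS_FLOOR),
        percent_identity=align.alignment_identity(alignment),
        log10_score=log10_as,
    )


@dataclass
class SimilarityNetwork:
    """Nodes plus scored edges kept at ``build_threshold``."""

    records: dict[str, ProteinRecord]
    edges: list[SimilarityEdge]
    build_threshold: float

    @property
    def accessions(self) -> list[str]:
        return list(self.records)

    def graph(self, cutoff: float | None = None) -> nx.Graph:
        """NetworkX view with edges at AS <= cutoff (default: all)."""
        log_cut = math.log10(cutoff if cutoff is not None
                             else self.build_threshold)
        g = nx.Graph()
        g.add_nodes_from(self.records)
        g.add_edges_from(
            (e.a, e.b, {"score": e.score, "log10_score": e.log10_score,
                        "percent_identity": e.percent_identity})
            for e in self.edges if e.log10_score <= log_cut)
        return g

    def write_tables(self, node_path: str | Path, edge_path: str | Path,
                     cutoff: float | None = None) -> None:
        """TSV node and edge tables importable by standard graph viewers."""
        g = self.graph(cutoff)
        comps = sorted(nx.connected_components(g), key=lambda c: min(c))
        with open(node_path, "w") as fh:
            fh.write("accession\tcomponent\tcomponent_size\n")
            for i, comp in enumerate(comps):
                for acc in sorted(comp):
                    fh.write(f"{acc}\t{i}\t{len(comp)}\n")
        with open(edge_path, "w") as fh:
            fh.write("a\tb\tscore\tlog10_score\tpercent_identity\n")
            for e in self.edges:
                if cutoff is None or e.log10_score <= math.log10(cutoff):
                    fh.write(f"{e.a}\t{e.b}\t{e.score:.6g}\t"
                             f"{e.log10_score:.4f}\t"
                             f"{e.percent_identity:.4f}\n")

    def write_graphml(self, path: str | Path,
                      cutoff: float | None = None) -> None:
        nx.write_graphml(self.graph(cutoff), str(path))


def build_network(
    records: Sequence[ProteinRecord],
    threshold: float = 1e-30,
    params: NetworkParams | None = None,
    length_window: tuple[int, int] = (150, 1100),
    kmer_prefilter: bool = False,
    kmer_size: int = 4,
) -> SimilarityNetwork:
    """All-vs-all network at an AS threshold.

    Records outside the customary length window trigger a warning (they
    should be filtered upstream).  ``kmer_prefilter`` optionally skips
    pairs sharing no k-mer — an admissible shortcut only for clearly
    unrelated pairs on large inputs; it is off by default.
    """
    params = params or NetworkParams()
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a network")
    out_of_window = [r.accession for r in records
                     if not length_window[0] <= len(r) <= length_window[1]]
    if out_of_window:
        warnings.warn(
            f"{len(out_of_window)} record(s) outside the "
            f"{length_window} length window (e.g. {out_of_window[0]})")
    by_acc: dict[str, ProteinRecord] = {}
    for r in records:
        if r.accession in by_acc:
            raise ValueError(f"duplicate accession {r.accession!r}")
        by_acc[r.accession] = r

    kmers = {r.accession: {r.sequence[i:i + kmer_size]
                           for i in range(len(r) - kmer_size + 1)}
             for r in records} if kmer_prefilter else None
    log_cut = math.log10(threshold)
    edges: list[SimilarityEdge] = []
    for x, y in combinations(records, 2):
        if kmers is not None and not (kmers[x.accession] & kmers[y.accession]):
            continue
        # fast score-only pass; full alignment only for retained edges
        raw = align.local_score(x.sequence, y.sequence, params.scoring)
        if _raw_to_log10_as(raw, len(x), len(y), params) <= log_cut:
            edges.append(score_pair(x, y, params))
    return SimilarityNetwork(by_acc, edges, threshold)


@dataclass
class SweepResult:
    """Connected components at each cut-off of a decreasing AS series."""

    cutoffs: list[float]
    components_at: dict[float, list[frozenset[str]]]
    #: per labeled seed group, first cutoff at which every component
    #: holding a group member is pure (group members only); None if never
    separation: dict[str, float | None] = field(default_factory=dict)

    def n_components(self, cutoff: float) -> int:
        return len(self.components_at[cutoff])


def sweep_components(
    network: SimilarityNetwork,
    cutoffs: Sequence[float],
    groups: Mapping[str, Iterable[str]] | None = None,
) -> SweepResult:
    """Follow cluster formation across strictly decreasing cut-offs.

    Components can only split as the cut-off decreases.  When ``groups``
    maps labels to accession sets (e.g. characterised seed sequences per
    CDH class), the result records each group's separation cut-off: the
    first cut-off at which no component mixes group members with
    outsiders.
    """
    cutoffs = list(cutoffs)
    if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly decreasing")
    if any(c > network.build_threshold for c in cutoffs):
        raise ValueError("cutoffs must not exceed the build threshold")
    components_at: dict[float, list[frozenset[str]]] = {}
    for cut in cutoffs:
        comps = [frozenset(c)
                 for c in nx.connected_components(network.graph(cut))]
        comps.sort(key=min)
        components_at[cut] = comps
    result = SweepResult(cutoffs, components_at)
    if groups:
        for label, members in groups.items():
            member_set = set(members)
            found = None
            for cut in cutoffs:
                holding = [c for c in components_at[cut] if c & member_set]
                if holding and all(c <= member_set for c in holding):
                    found = cut
                    break
            result.separation[label] = found
    return result


@dataclass
class ExtractionResult:
    records: list[ProteinRecord]
    cutoff: float
    seeds: list[str]

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]


def extract_cluster(
    network: SimilarityNetwork,
    cutoff: float,
    seeds: Iterable[str],
) -> ExtractionResult:
    """All members of the component(s) containing the seeds at a cut-off.

    This is the step that pulls every sequence co-clustering with the
    characterised seeds out of the network (e.g. the class III cluster at
    1e-160) for downstream curation.
    """
    seeds = list(seeds)
    for s in seeds:
        if s not in network.records:
            raise KeyError(f"unknown seed accession {s!r}")
    g = network.graph(cutoff)
    members: set[str] = set()
    for comp in nx.connected_components(g):
        if comp & set(seeds):
            members |= comp
    return ExtractionResult(
        [network.records[a] for a in sorted(members)], cutoff, seeds)
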