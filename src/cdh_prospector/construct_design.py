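"""Golden-gate construct design: domestication, fragmentation, assembly.

A selected coding sequence is turned into synthesis-ready modules in five
steps: (i) forbidden restriction sites (SacI, PmeI, AscI, BbsI, BsaI) are
destroyed by synonymous codon exchanges, (ii) the terminal stop codon is
removed, (iii) the gene is cut at the domain boundaries (SP / Cyt / DH)
mapped from the protein-level split, with oversized parts subdivided and
undersized parts padded by a neutral spacer so every synthesized fragment
falls in the 300–900 bp window vendors accept, (iv) each junction receives
a unique, non-palindromic 4-nt fusion overhang, and (v) the plan is
validated by simulating the Type IIS digestion/ligation one-pot reaction
and checking that the unique linear product reconstructs the domesticated
CDS followed by the TAA stop module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import NucleotideRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition sequence plus Type IIS cut geometry.

    ``cut_offset`` is the distance from the 3' end of the recognition
    sequence to the top-strand cut; ``overhang`` the length of the 5'
    overhang produced.  Blunt/within-site cutters used only for scanning
    leave both at None.
    """

    name: str
    recognition: str
    cut_offset: int | None = None
    overhang: int | None = None

    def __post_init__(self) -> None:
        if set(self.recognition) - set("ACGT"):
            raise ValueError(f"{self.name}: recognition must be over ACGT")

    @property
    def palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


SACI = RestrictionEnzyme("SacI", "GAGCTC")
PMEI = RestrictionEnzyme("PmeI", "GTTTAAAC")
ASCI = RestrictionEnzyme("AscI", "GGCGCGCC")
BBSI = RestrictionEnzyme("BbsI", "GAAGAC", cut_offset=2, overhang=4)
BSAI = RestrictionEnzyme("BsaI", "GGTCTC", cut_offset=1, overhang=4)

#: the five sites removed during domestication
DEFAULT_ENZYMES = (SACI, PMEI, ASCI, BBSI, BSAI)

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: stop-module payload: TAA stop codon plus the standard CDS-3' fusion tail
STOP_PAYLOAD = "TAAGCTT"
#: acceptor-side overhang downstream of the stop module
VECTOR_3_OVERHANG = "CGCT"

_ADAPTER_5 = "TT" + BSAI.recognition + "A"          # BsaI pointing inward
_ADAPTER_3 = "T" + revcomp(BSAI.recognition) + "AA"  # BsaI on the - strand


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    start: int          # 0-based on the + strand
    strand: str         # '+' or '-'


def scan_restriction_sites(
    dna: NucleotideRecord | str,
    enzymes: Iterable[RestrictionEnzyme] = DEFAULT_ENZYMES,
) -> list[RestrictionSite]:
    """All recognition-site occurrences on both strands.

    Overlapping occurrences are reported; palindromic sites once.
    """
    seq = dna.sequence if isinstance(dna, NucleotideRecord) else dna
    sites: list[RestrictionSite] = []
    for enz in enzymes:
        for m in re.finditer(f"(?=({enz.recognition}))", seq):
            sites.append(RestrictionSite(enz.name, m.start(), "+"))
        if not enz.palindromic:
            for m in re.finditer(f"(?=({revcomp(enz.recognition)}))", seq):
                sites.append(RestrictionSite(enz.name, m.start(), "-"))
    sites.sort(key=lambda s: (s.start, s.enzyme, s.strand))
    return sites


def _synonymous_codons(codon: str) -> list[str]:
    aa = STANDARD_TABLE.forward_table.get(codon)
    if aa is None:
        return []
    return sorted(c for c, a in STANDARD_TABLE.forward_table.items()
                  if a == aa and c != codon)


@dataclass
class CodonEdit:
    codon_index: int
    before: str
    after: str
    site: RestrictionSite


class DomesticationError(ValueError):
    """A forbidden site cannot be removed synonymously."""


def _rank_codon(codon: str, usage: dict[str, float] | None) -> tuple:
    freq = (usage or {}).get(codon, 0.0)
    return (-freq, codon)


def domesticate_cds(
    cds: NucleotideRecord,
    enzymes: Iterable[RestrictionEnzyme] = DEFAULT_ENZYMES,
    codon_usage: dict[str, float] | None = None,
    max_rounds: int = 200,
) -> tuple[NucleotideRecord, list[CodonEdit]]:
    """Remove forbidden sites by synonymous codon exchange; strip the stop.

    Each site is destroyed with the minimal number of codon changes (single
    exchanges tried before pairs); among equally minimal options the codon
    most frequent in ``codon_usage`` wins (uniform default, alphabetical
    tie-break).  The translation of the result plus a stop codon equals the
    input translation, and a re-scan finds zero sites.
    """
    enzymes = tuple(enzymes)
    seq = cds.sequence
    if len(seq) % 3:
        raise ValueError(f"{cds.accession}: CDS length not divisible by 3")
    protein = str(Seq(seq).translate(table=STANDARD_TABLE))
    if "*" in protein[:-1]:
        raise ValueError(f"{cds.accession}: internal stop codon")
    if protein.endswith("*"):
        seq = seq[:-3]
        protein = protein[:-1]

    edits: list[CodonEdit] = []
    for _ in range(max_rounds):
        sites = scan_restriction_sites(seq, enzymes)
        if not sites:
            break
        site = sites[0]
        enz = next(e for e in enzymes if e.name == site.enzyme)
        span = (site.start, site.start + len(enz.recognition))
        first = span[0] // 3
        last = (span[1] - 1) // 3
        candidates = []
        for n_changed in (1, 2):
            for idxs in combinations(range(first, last + 1), n_changed):
                options = [_synonymous_codons(seq[i * 3:i * 3 + 3])
                           for i in idxs]
                if any(not o for o in options):
                    continue
                for combo in product(*options):
                    trial = list(seq)
                    for i, new in zip(idxs, combo):
                        trial[i * 3:i * 3 + 3] = new
                    trial_seq = "".join(trial)
                    new_sites = scan_restriction_sites(trial_seq, enzymes)
                    if len(new_sites) < len(sites) and site not in new_sites:
                        rank = tuple(_rank_codon(c, codon_usage)
                                     for c in combo)
                        candidates.append((n_changed, rank, idxs, combo,
                                           trial_seq))
            if candidates:
                break
        if not candidates:
            raise DomesticationError(
                f"{cds.accession}: site {site.enzyme} at {site.start} has "
                "no synonymous escape")
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, _, idxs, combo, new_seq = candidates[0]
        for i, new in zip(idxs, combo):
            edits.append(CodonEdit(i, seq[i * 3:i * 3 + 3], new, site))
        seq = new_seq
    else:
        raise DomesticationError(f"{cds.accession}: domestication did not "
                                 f"converge in {max_rounds} rounds")

    assert str(Seq(seq).translate(table=STANDARD_TABLE)) == protein
    return (NucleotideRecord(cds.accession, seq,
                             cds.description + " [domesticated]"),
            edits)


# ---------------------------------------------------------------------------
# fragment planning

def make_spacer(length: int,
                enzymes: Iterable[RestrictionEnzyme] = DEFAULT_ENZYMES) -> str:
    """Deterministic neutral padding free of every forbidden site."""
    enzymes = tuple(enzymes)
    seq = ""
    for _ in range(length):
        for base in "CATG":
            trial = seq + base
            window = trial[-16:]
            if not scan_restriction_sites(window, enzymes):
                seq = trial
                break
        else:  # pragma: no cover - four bases always offer an escape
            raise RuntimeError("spacer construction failed")
    return seq


@dataclass
class FragmentPlan:
    """One synthesis-ready golden-gate module.

    ``sequence`` is the full synthesized string (adapters + payload +
    fusion overhang + optional spacer); ``payload`` the CDS slice it
    contributes to the final ORF.  The 4-nt ``left_overhang`` equals the
    payload's first 4 nt; ``right_overhang`` is the first 4 nt of the
    *next* module's payload and is carried inside this fragment so the
    Type IIS cut releases it as the sticky end.
    """

    label: str
    payload: str
    left_overhang: str
    right_overhang: str
    five_flank: str = _ADAPTER_5
    three_flank: str = _ADAPTER_3
    spacer: str = ""
    payload_interval: tuple[int, int] = (0, 0)  # 0-based, half-open, bp

    @property
    def sequence(self) -> str:
        return (self.five_flank + self.payload + self.right_overhang
                + self.three_flank + self.spacer)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def spacer_used(self) -> bool:
        return bool(self.spacer)


@dataclass
class DomainBoundaries:
    """Protein-level split (1-based residues): SP ends at ``sp_end``, the
    DH domain starts at ``dh_start`` (eight residues before YDY)."""

    sp_end: int
    dh_start: int


class PlanningError(ValueError):
    pass


def _is_palindrome(oh: str) -> bool:
    return oh == revcomp(oh)


def plan_fragments(
    cds: NucleotideRecord,
    boundaries: DomainBoundaries,
    min_len: int = 300,
    max_len: int = 900,
) -> list[FragmentPlan]:
    """Partition a domesticated, stop-less CDS into golden-gate modules.

    Cuts fall on codon boundaries at the SP|Cyt and Cyt|DH splits; any
    segment whose synthesized form would exceed ``max_len`` is subdivided
    at codon boundaries, and any below ``min_len`` is padded with a
    neutral 3' spacer.  Every junction overhang must be unique and
    non-palindromic; cut points shift by whole codons (up to 10) when a
    junction 4-mer violates that.  A terminal stop module (TAA plus
    fusion tail) completes the plan.
    """
    seq = cds.sequence
    if len(seq) % 3:
        raise ValueError("CDS length must be divisible by 3")
    n = len(seq)
    sp_cut = boundaries.sp_end * 3
    dh_cut = (boundaries.dh_start - 1) * 3
    if not 0 < sp_cut < dh_cut < n:
        raise PlanningError("boundaries must satisfy 0 < SP end < DH start "
                            "< CDS end (with >= 1 codon per domain)")

    adapter_len = len(_ADAPTER_5) + 4 + len(_ADAPTER_3)
    max_payload = max_len - adapter_len

    segments: list[tuple[str, int, int]] = []
    for label, lo, hi in (("SP", 0, sp_cut), ("Cyt", sp_cut, dh_cut),
                          ("DH", dh_cut, n)):
        if hi - lo > max_payload:
            length = hi - lo
            parts = -(-length // max_payload)  # ceil division
            while True:  # balanced codon-multiple part size
                size = -(-length // (parts * 3)) * 3
                if size <= max_payload:
                    break
                parts += 1
            for i in range(parts):
                s = lo + i * size
                e = hi if i == parts - 1 else s + size
                segments.append((f"{label}_{i + 1}", s, e))
        else:
            segments.append((label, lo, hi))

    extended = seq + STOP_PAYLOAD

    def overhang_at(cut: int) -> str:
        return extended[cut:cut + 4]

    # shift interior cuts (not 0, not n) until all overhangs are unique
    # and non-palindromic
    cuts = [lo for _, lo, _ in segments] + [n]
    labels = [lab for lab, _, _ in segments]
    taken = {VECTOR_3_OVERHANG, overhang_at(cuts[0])}
    if _is_palindrome(overhang_at(cuts[0])):
        raise PlanningError("start codon overhang is palindromic")
    for i in range(1, len(cuts)):
        fixed = cuts[i] == n  # the stop-module junction cannot move
        for shift in ([0] if fixed else
                      [0, 3, -3, 6, -6, 9, -9, 12, -12, 15, -15,
                       18, -18, 21, -21, 24, -24, 27, -27, 30, -30]):
            cand = cuts[i] + shift
            if not cuts[i - 1] + 3 <= cand <= (n if fixed else n - 3):
                continue
            oh = overhang_at(cand)
            if oh not in taken and not _is_palindrome(oh):
                cuts[i] = cand
                taken.add(oh)
                break
        else:
            raise PlanningError(
                f"no unique non-palindromic overhang near junction {i}")

    plans: list[FragmentPlan] = []
    for i, label in enumerate(labels):
        lo, hi = cuts[i], cuts[i + 1]
        payload = seq[lo:hi]
        frag = FragmentPlan(
            label=label, payload=payload,
            left_overhang=payload[:4],
            right_overhang=overhang_at(hi),
            payload_interval=(lo, hi),
        )
        if frag.length < min_len:
            frag.spacer = make_spacer(min_len - frag.length)
        if not min_len <= frag.length <= max_len:
            raise PlanningError(
                f"{label}: synthesized length {frag.length} outside "
                f"[{min_len}, {max_len}]")
        plans.append(frag)

    stop = FragmentPlan(
        label="stop", payload=STOP_PAYLOAD,
        left_overhang=STOP_PAYLOAD[:4],
        right_overhang=VECTOR_3_OVERHANG,
        payload_interval=(n, n + len(STOP_PAYLOAD)),
    )
    if stop.length < min_len:
        stop.spacer = make_spacer(min_len - stop.length)
    plans.append(stop)
    return plans


# ---------------------------------------------------------------------------
# in-silico assembly

@dataclass
class DigestedPiece:
    label: str
    left_overhang: str
    body: str            # top strand from left overhang up to right overhang
    right_overhang: str


class AssemblyError(ValueError):
    pass


def digest(fragment: FragmentPlan | str, label: str = "",
           enzyme: RestrictionEnzyme = BSAI) -> DigestedPiece:
    """Simulate the Type IIS double cut on one synthesized fragment."""
    if isinstance(fragment, FragmentPlan):
        seq, label = fragment.sequence, fragment.label
    else:
        seq = fragment
    fwd = seq.find(enzyme.recognition)
    rev = seq.find(revcomp(enzyme.recognition))
    if fwd < 0 or rev < 0 or rev <= fwd:
        raise AssemblyError(f"{label}: fragment lacks properly oriented "
                            f"{enzyme.name} sites")
    start = fwd + len(enzyme.recognition) + enzyme.cut_offset
    end = rev - enzyme.cut_offset
    retained = seq[start:end]
    if len(retained) < 2 * enzyme.overhang:
        raise AssemblyError(f"{label}: digested insert too short")
    return DigestedPiece(label, retained[:enzyme.overhang],
                         retained[:-enzyme.overhang],
                         retained[-enzyme.overhang:])


@dataclass
class AssemblyReport:
    valid: bool
    product: str
    fragment_order: list[str]
    message: str
    first_divergence: int | None = None


def validate_assembly(
    plan: Sequence[FragmentPlan],
    expected_cds: NucleotideRecord | str | None = None,
) -> AssemblyReport:
    """Simulate the one-pot digestion/ligation and check the product.

    Fragment input order is irrelevant: pieces chain purely by overhang
    complementarity.  Duplicate overhangs make the ligation ambiguous and
    raise; a mismatch against ``expected_cds`` (+ stop payload) is
    reported with the first divergent position.
    """
    pieces = [digest(f) for f in plan]
    lefts = [p.left_overhang for p in pieces]
    rights = [p.right_overhang for p in pieces]
    if len(set(lefts)) != len(lefts):
        raise AssemblyError("ambiguous ligation: duplicate left overhangs")
    if len(set(rights)) != len(rights):
        raise AssemblyError("ambiguous ligation: duplicate right overhangs")
    by_left = {p.left_overhang: p for p in pieces}
    starts = [p for p in pieces if p.left_overhang not in set(rights)]
    if len(starts) != 1:
        raise AssemblyError(f"expected one chain start, found {len(starts)}")
    chain = [starts[0]]
    while chain[-1].right_overhang in by_left:
        nxt = by_left[chain[-1].right_overhang]
        if nxt in chain:
            raise AssemblyError("circular ligation product")
        chain.append(nxt)
    if len(chain) != len(pieces):
        raise AssemblyError("fragments do not form a single linear product")
    product = "".join(p.body for p in chain) + chain[-1].right_overhang
    # drop the acceptor-side tail overhang: the ORF ends with the stop
    # module payload
    if product.endswith(VECTOR_3_OVERHANG):
        product = product[:-len(VECTOR_3_OVERHANG)]
    order = [p.label for p in chain]
    if expected_cds is not None:
        exp = (expected_cds.sequence
               if isinstance(expected_cds, NucleotideRecord) else expected_cds)
        expected = exp + STOP_PAYLOAD
        if product != expected:
            div = next((i for i, (a, b) in enumerate(zip(product, expected))
                        if a != b), min(len(product), len(expected)))
            return AssemblyReport(False, product, order,
                                  f"product differs from expected ORF at "
                                  f"position {div}", div)
        stop_codon = product[len(exp):len(exp) + 3]
        if stop_codon not in STANDARD_TABLE.stop_codons:
            return AssemblyReport(False, product, order,
                                  "ORF does not end with a stop codon")
    return AssemblyReport(True, product, order, "assembly valid")
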