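"""A synthetic annotated reference protein for anchoring and testing.

The curation criteria are defined relative to a biochemically characterised
class I CDH whose published numbering places the heme ligands at Met65 and
His163, the catalytic histidine at His689, and the YDY linker anchor just
ahead of the Rossmann GxGxxG motif at the dehydrogenase-domain start.  The
record built here is *synthetic*: a deterministic, seeded random protein of
the same length and domain layout with every annotated feature planted at
exactly those coordinates.  It exercises the full anchoring machinery with
known ground truth; for work on real data, supply your own annotated
reference via :class:`~cdh_prospector.curation.ReferenceAnnotation`.
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np

from .curation import ReferenceAnnotation
from .seqio import ProteinRecord

#: Robinson–Robinson style background amino-acid frequencies
BACKGROUND = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.065, "W": 0.014, "Y": 0.032,
}

REFERENCE_LENGTH = 770
SP_END = 18
HEME_MET = 65
HEME_HIS = 163
YDY_START = 238
ROSSMANN_START = 246
CATALYTIC_HIS = 689
CYT_REGION = (19, 215)
DH_REGION = (230, 770)

_SIGNAL_PEPTIDE = "MKWVTFISLLFLFSSAYS"          # canonical n/h/c leader
_MATURE_NTERM = "DTNQTEPA"                      # polar mature N-terminus
_ROSSMANN = "GSGPIG"                            # matches G-x-G-x-x-G

_REFERENCE_SEED = 20240317


def _scrub(seq: list[str], pattern: str, keep_start: int,
           lo: int, hi: int) -> None:
    """Destroy accidental pattern matches in [lo, hi) except at keep_start
    (all 0-based), so planted motifs stay the unique hits in their search
    windows."""
    while True:
        text = "".join(seq)
        for m in re.finditer(f"(?=({pattern}))", text[lo:hi]):
            start = lo + m.start()
            if start == keep_start:
                continue
            # mutate the middle of the offending match to a residue that
            # cannot re-create the pattern
            seq[start + 1] = "N" if seq[start + 1] != "N" else "Q"
            break
        else:
            return


@lru_cache(maxsize=1)
def synthetic_reference_record() -> ProteinRecord:
    """The deterministic synthetic reference sequence (770 residues)."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    letters = list(BACKGROUND)
    probs = np.array([BACKGROUND[a] for a in letters])
    probs = probs / probs.sum()
    seq = list(rng.choice(letters, size=REFERENCE_LENGTH, p=probs))

    seq[0:len(_SIGNAL_PEPTIDE)] = list(_SIGNAL_PEPTIDE)
    seq[SP_END:SP_END + len(_MATURE_NTERM)] = list(_MATURE_NTERM)
    seq[HEME_MET - 1] = "M"
    seq[HEME_HIS - 1] = "H"
    seq[YDY_START - 1:YDY_START + 2] = list("YDY")
    seq[ROSSMANN_START - 1:ROSSMANN_START + 5] = list(_ROSSMANN)
    seq[CATALYTIC_HIS - 1] = "H"

    # keep the planted motifs unique within the windows the curation
    # criteria search, so single-point ablations flip the criteria cleanly
    _scrub(seq, "YDY", YDY_START - 1,
           max(0, YDY_START - 1 - 25), YDY_START - 1 + 28)
    _scrub(seq, "G.G..G", ROSSMANN_START - 1,
           max(0, ROSSMANN_START - 1 - 20), ROSSMANN_START - 1 + 26)

    return ProteinRecord(
        accession="SYNREF_CDH1",
        sequence="".join(seq),
        description="synthetic annotated class I CDH-like reference",
        class_label="I",
    )


def synthetic_reference_annotation() -> ReferenceAnnotation:
    """The synthetic reference with its full annotation."""
    return ReferenceAnnotation(
        reference=synthetic_reference_record(),
        heme_met_pos=HEME_MET,
        heme_his_pos=HEME_HIS,
        catalytic_his_pos=CATALYTIC_HIS,
        cyt_region=CYT_REGION,
        dh_region=DH_REGION,
    )
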