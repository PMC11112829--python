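"""Independent affine-gap Smith–Waterman oracle for tiny inputs.

Pure-NumPy Gotoh recursion, written separately from the package's aligner:
the first residue of a gap costs ``gap_open``, each extension
``gap_extend``.
"""

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def gotoh_local(x: str, y: str, gap_open: float = 11.0,
                gap_extend: float = 1.0) -> float:
    n, m = len(x), len(y)
    neg = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)   # gap in y (vertical move)
    Iy = np.full((n + 1, m + 1), neg)   # gap in x (horizontal move)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM[x[i - 1], y[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                       Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] - gap_open,
                           Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open,
                           Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return float(best)
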