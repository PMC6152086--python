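"""Canonical amino-acid column order and substitution matrices.

Every R x 20 profile matrix in this package uses the same fixed column
order, declared once here.  It is the PSI-BLAST ASCII profile order, so
files written by PSI-BLAST parse without any column shuffling.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: Fixed column order shared by PSSMs, mutation matrices and the
#: synthetic generator (PSI-BLAST profile order).
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Letter -> column index under :data:`AA_ORDER`.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

#: Residue codes tolerated in sequences but absent from the 20-letter
#: alphabet (ambiguity codes, selenocysteine/pyrrolysine, gaps, stops).
NONCANONICAL: frozenset[str] = frozenset("BZXJUO*-")


def dayhoff_matrix(name: str = "PAM250") -> np.ndarray:
    """Return a 20 x 20 Dayhoff-family substitution matrix.

    The matrix is loaded from Biopython's curated collection and
    reordered to :data:`AA_ORDER` on both axes, so that entry ``[v, k]``
    is the substitution score w(v, k) between the v-th and k-th amino
    acids under the package-wide column convention.  PAM250 is the
    default; any matrix name Biopython ships (e.g. ``"PAM30"``,
    ``"BLOSUM62"``) is accepted.
    """
    mat = substitution_matrices.load(name)
    idx = [mat.alphabet.index(a) for a in AA_ORDER]
    return np.asarray(mat)[np.ix_(idx, idx)].astype(float)
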