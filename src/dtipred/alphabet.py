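"""Amino-acid alphabet conventions shared across the package.

All protein features index the 20 native amino acids in full alphabetical
single-letter order. PSI-BLAST ASCII PSSM files print their 20 score columns
in a different, fixed order; readers remap to the canonical order on input.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order used for every 20-wide feature block.
CANONICAL_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the first 20 score columns in PSI-BLAST ``-out_ascii_pssm``.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Residue -> canonical column index.
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ORDER)}

#: Ambiguity / non-standard codes rejected (or dropped on opt-in) by readers.
NON_STANDARD = set("BJOUXZ")

#: Ordered dipeptides (first, second) lexicographic in canonical order; 400 entries.
DIPEPTIDES = tuple(a + b for a in CANONICAL_ORDER for b in CANONICAL_ORDER)

DIPEPTIDE_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}

#: Permutation p with scores_canonical[:, i] = scores_psiblast[:, p[i]].
PSIBLAST_TO_CANONICAL = np.array(
    [PSIBLAST_ORDER.index(aa) for aa in CANONICAL_ORDER], dtype=np.intp
)

#: Inverse permutation, restoring PSI-BLAST file order from canonical order.
CANONICAL_TO_PSIBLAST = np.argsort(PSIBLAST_TO_CANONICAL)
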