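"""Integer genotype codes shared across the package.

Calls are stored as int8: ``AA`` is the homozygote for the A allele (the
recurrent/cultivar parent, "Af"), ``BB`` for the B allele (the wild donor
parent, "Ws"), ``HET`` a heterozygote and ``MISSING`` an uncalled entry.
In unoriented matrices read from VCF, A temporarily means the reference
allele and B the alternate; :func:`bilqtl.panel.filter_snps` orients codes
so that A is always the recurrent-parent allele.
"""

from __future__ import annotations

import numpy as np

MISSING: int = -1
AA: int = 0
HET: int = 1
BB: int = 2

#: letters used by the TSV matrix dialect
LETTER = {AA: "A", HET: "H", BB: "B", MISSING: "."}
CODE = {v: k for k, v in LETTER.items()}


def score(codes: np.ndarray, missing: float = 0.0) -> np.ndarray:
    """Additive genotype score: AA -> +1, BB -> -1, HET -> 0.

    ``missing`` is the value substituted for uncalled entries (0 treats them
    as uninformative; ``np.nan`` propagates missingness).
    """
    codes = np.asarray(codes)
    x = np.where(codes == AA, 1.0, np.where(codes == BB, -1.0, 0.0))
    if missing != 0.0 or np.isnan(missing):
        x = np.where(codes == MISSING, missing, x)
    return x
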