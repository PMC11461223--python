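"""Pyrosequencing assay-sequence parsing.

In a bisulfite pyrosequencing dispensation sequence, assayed CpG cytosines
appear as the IUPAC degenerate symbol Y (C or T): after bisulfite conversion
an unmethylated cytosine reads as T and a methylated one as C, so each Y
marks one quantified CpG site. The MB-COMT promoter assay sequence
5'-TYGGGYGGGTYGTYGYGGGAGAGGTGAGAG-3' therefore carries five assayed sites.
"""

from __future__ import annotations

from .errors import FormatError

_ALLOWED = frozenset("ACGTYRN")


def find_cpg_positions(assay_sequence: str) -> list[int]:
    """1-based positions of assayed CpG cytosines (Y symbols), ascending.

    Parameters
    ----------
    assay_sequence
        Nucleotide string over {A, C, G, T, Y, R, N} (case-insensitive).

    Returns
    -------
    list of int
        Positions of every Y in the sequence; its length equals the number
        of CpG sites the assay quantifies.
    """
    seq = assay_sequence.strip().upper()
    bad = set(seq) - _ALLOWED
    if bad:
        raise FormatError(
            f"illegal characters in assay sequence: {sorted(bad)!r}"
        )
    return [i + 1 for i, base in enumerate(seq) if base == "Y"]
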