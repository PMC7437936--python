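"""Small published reference tables bundled with the package.

The HeLa tables below hold poly(A)-tail occurrences of the parental
genes of experimentally confirmed HeLa fusion transcripts, as measured
by TAIL-seq (tail counts per gene, after in-depth re-alignment of the
poly(A)-containing reads). They are the standard worked example for the
poly(A) mechanism classifier: chimeras produced by cis-SAGe or genomic
gene fusion silence the 5' gene's tail, trans-splicing chimeras keep
both parental tails.

``TXNDC9-LYG1`` is the documented discordant case: both genes carry
tails despite a confirmed chimera, explained by a megabase-scale
inversion on chromosome 2 spanning both loci rather than by
trans-splicing. ``GFOD2-ENKD1`` and ``MFSD7-ATP5I`` had no tails
detected for either gene.
"""

from __future__ import annotations

__all__ = [
    "HELA_FUSION_PAIRS",
    "HELA_TRANS_SPLICING_PAIRS",
    "HELA_UNDETECTED_PAIRS",
    "HELA_TAIL_COUNTS",
]

# (gene5, gene3) -> (tails on 5' gene, tails on 3' gene)
# confirmed cis-SAGe / genomic gene fusions
HELA_FUSION_PAIRS: dict[tuple[str, str], tuple[int, int]] = {
    ("FOXRED2", "TXN2"): (0, 340),
    ("LHX6", "NDUFA8"): (0, 218),
    ("SLC2A11", "MIF"): (0, 842),
    ("SLC45A3", "ELK4"): (0, 5),
    ("TXNDC9", "LYG1"): (10, 30),  # inversion case, see module docstring
    ("UBE2Q2", "FBXO22"): (0, 97),
}

# chimeras attributed to trans-splicing: both parents polyadenylated
HELA_TRANS_SPLICING_PAIRS: dict[tuple[str, str], tuple[int, int]] = {
    ("DHRS13", "FLOT2"): (64, 71),
    ("TINF2", "NEDD8"): (35, 69),
    ("VMP1", "RPS6KB1"): (51, 48),
}

# confirmed chimeras with no tails detected on either parent
HELA_UNDETECTED_PAIRS: dict[tuple[str, str], tuple[int, int]] = {
    ("GFOD2", "ENKD1"): (0, 0),
    ("MFSD7", "ATP5I"): (0, 0),
}


def _flatten(*tables) -> dict[str, int]:
    out: dict[str, int] = {}
    for table in tables:
        for (g5, g3), (c5, c3) in table.items():
            out[g5] = c5
            out[g3] = c3
    return out


#: gene -> tail count over all pairs above, in ``read_polya_table`` form
HELA_TAIL_COUNTS: dict[str, int] = _flatten(
    HELA_FUSION_PAIRS, HELA_TRANS_SPLICING_PAIRS, HELA_UNDETECTED_PAIRS
)
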