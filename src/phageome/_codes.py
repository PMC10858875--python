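"""Genetic-code tables used for phage gene translation.

Phage genomes frequently reassign stop codons.  Besides the standard
bacterial code (11) we support the three stop-recoded variants seen in
gut phage genomes: TGA->Trp (4), TGA->Gly (25), TAG->Gln (15) and
TAA->Gln (91).  Code 91 is a stop-reassignment convention used by gene
callers rather than an NCBI translation table, so it is built here from
code 11.
"""

from __future__ import annotations

from Bio.Data import CodonTable

SUPPORTED_CODES = (11, 4, 25, 15, 91)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _table_from_ncbi(table_id: int) -> dict[str, str]:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    table = dict(ncbi.forward_table)
    for codon in ncbi.stop_codons:
        table[codon] = "*"
    return table


def _build(code: int) -> dict[str, str]:
    if code == 91:
        table = _table_from_ncbi(11)
        table["TAA"] = "Q"
        return table
    if code == 25:
        # TGA -> Gly (SR1/Gracilibacteria), NCBI table 25
        return _table_from_ncbi(25)
    if code in (4, 11, 15):
        return _table_from_ncbi(code)
    raise ValueError(f"unsupported genetic code: {code}")


_TABLES: dict[int, dict[str, str]] = {c: _build(c) for c in SUPPORTED_CODES}


def codon_table(code: int) -> dict[str, str]:
    """Return the codon->amino-acid map (stops as ``*``) for a code id."""
    try:
        return _TABLES[code]
    except KeyError:
        raise ValueError(f"unsupported genetic code: {code}") from None


def translate(seq: str, code: int = 11) -> str:
    """Translate a nucleotide sequence in frame 0; trailing partial codon dropped."""
    table = codon_table(code)
    seq = seq.upper()
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa.append(table.get(seq[i : i + 3], "X"))
    return "".join(aa)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
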