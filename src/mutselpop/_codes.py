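"""Standard genetic code tables and single-nucleotide neighbourhood arrays.

Everything downstream indexes codons as integers 0..60 over the 61 sense
codons (alphabetical order) and amino acids as integers 0..19 over the 20
one-letter codes in alphabetical order. The neighbourhood arrays enumerate,
for every sense codon, its nine single-nucleotide changes; changes into stop
codons are flagged rather than dropped so that opportunity accounting can
exclude them explicitly.
"""
from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_table = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in _table.forward_table if set(c) <= set(NUCLEOTIDES)))
assert len(SENSE_CODONS) == 61 and len(STOP_CODONS) == 3

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino-acid index (0..19) of each sense codon
CODON_AA = np.array([AA_INDEX[_table.forward_table[c]] for c in SENSE_CODONS], dtype=np.int64)

N_CODONS = 61
N_CHANGES = 9  # 3 positions x 3 alternative nucleotides

# Neighbourhood arrays, all shaped (61, 9).
NEI_TARGET = np.full((N_CODONS, N_CHANGES), -1, dtype=np.int64)  # -1 => stop codon
NEI_POS = np.zeros((N_CODONS, N_CHANGES), dtype=np.int64)
NEI_FROM_NT = np.zeros((N_CODONS, N_CHANGES), dtype=np.int64)
NEI_TO_NT = np.zeros((N_CODONS, N_CHANGES), dtype=np.int64)
NEI_IS_STOP = np.zeros((N_CODONS, N_CHANGES), dtype=bool)
NEI_IS_SYN = np.zeros((N_CODONS, N_CHANGES), dtype=bool)
NEI_AA_TO = np.full((N_CODONS, N_CHANGES), -1, dtype=np.int64)

for _c, _codon in enumerate(SENSE_CODONS):
    _j = 0
    for _pos in range(3):
        for _nt in NUCLEOTIDES:
            if _nt == _codon[_pos]:
                continue
            _target = _codon[:_pos] + _nt + _codon[_pos + 1:]
            NEI_POS[_c, _j] = _pos
            NEI_FROM_NT[_c, _j] = NT_INDEX[_codon[_pos]]
            NEI_TO_NT[_c, _j] = NT_INDEX[_nt]
            if _target in STOP_CODONS:
                NEI_IS_STOP[_c, _j] = True
            else:
                _t = CODON_INDEX[_target]
                NEI_TARGET[_c, _j] = _t
                NEI_IS_SYN[_c, _j] = CODON_AA[_t] == CODON_AA[_c]
                NEI_AA_TO[_c, _j] = CODON_AA[_t]
            _j += 1

#: nucleotide index (0..3) of each sense codon at each of its 3 positions
CODON_NT = np.array([[NT_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS], dtype=np.int64)


class GeneticCode:
    """The standard genetic code over 61 sense codons and 3 stops.

    A thin object wrapper over the module-level tables, kept so that the
    translation rules used everywhere are inspectable in one place.
    """

    codons = SENSE_CODONS
    stops = STOP_CODONS
    amino_acids = AMINO_ACIDS

    @staticmethod
    def translate(codon: str) -> str:
        return AMINO_ACIDS[CODON_AA[CODON_INDEX[codon]]]

    @staticmethod
    def codon_index(codon: str) -> int:
        """Index of a sense codon, or -1 for gaps/ambiguous/stop codons."""
        return CODON_INDEX.get(codon.upper().replace("U", "T"), -1)

    @staticmethod
    def is_synonymous(a: str, b: str) -> bool:
        return GeneticCode.translate(a) == GeneticCode.translate(b)


def codons_differ_at(a: int, b: int) -> list[int]:
    """Positions (0..2) at which two sense codons differ."""
    ca, cb = SENSE_CODONS[a], SENSE_CODONS[b]
    return [p for p in range(3) if ca[p] != cb[p]]
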