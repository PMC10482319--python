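"""Genetic-code helpers and illustrative codon weight tables.

The standard genetic code is taken from Biopython's codon tables. The
example weight tables constructed here are clearly synthetic/illustrative:
they follow the classic convention (the preferred codon of each synonymous
family has weight 1.0; less-preferred codons have geometrically decreasing
weights) but are NOT the published reference weights for any organism.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons of the standard code
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: the three stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: 61 sense codons, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of its synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: amino acids encoded by more than one codon (carry codon-bias signal)
MULTI_CODON_AAS: tuple[str, ...] = tuple(
    aa for aa, codons in sorted(AA_TO_CODONS.items()) if len(codons) > 1
)


def example_weights(decay: float = 0.5) -> dict[str, float]:
    """Build an illustrative CAI-style weight map over the 61 sense codons.

    Within each synonymous family the alphabetically first codon gets
    weight 1.0 and each subsequent codon is down-weighted by ``decay``:
    w = decay**rank. Single-codon families (Met, Trp) get 1.0, the classic
    convention. Deterministic; for demonstrations and simulations only.
    """
    if not 0 < decay <= 1:
        raise ValueError("decay must be in (0, 1]")
    weights: dict[str, float] = {}
    for codons in AA_TO_CODONS.values():
        for rank, codon in enumerate(codons):
            weights[codon] = decay**rank
    return weights
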