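"""Genetic code tables and synonymous-family structure.

Wraps Biopython's NCBI codon tables into the family-oriented view that codon
usage statistics need: amino acid -> synonymous codon list, degeneracy
classes, and the set of synonymously variable ("degenerate") codons.

Codons are handled as DNA uppercase strings internally; :func:`to_rna` /
:func:`to_dna` convert for display and for RNA-keyed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP = "*"


def to_rna(codon: str) -> str:
    """DNA codon -> RNA codon (T->U)."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    """RNA codon -> DNA codon (U->T)."""
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code as synonymous codon families.

    Attributes
    ----------
    table_id : int
        NCBI translation table number (1 = standard; plant mitochondria use
        the standard code).
    codon_to_aa : dict
        Maps all 64 codons to a one-letter amino acid or ``"*"`` for stop.
    families : dict
        Amino acid -> tuple of synonymous codons (sorted), stops excluded.
    stop_codons : frozenset
        The stop codons of the table.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]
    stop_codons: frozenset[str]
    name: str = field(default="", compare=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = STOP
        families: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            families.setdefault(aa, []).append(codon)
        fams = {aa: tuple(sorted(cods)) for aa, cods in sorted(families.items())}
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            families=fams,
            stop_codons=frozenset(table.stop_codons),
            name=table.names[0] if table.names else str(table_id),
        )

    # -- family structure ---------------------------------------------------

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    @property
    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Degeneracy k -> amino acids whose family has k codons."""
        out: dict[int, list[str]] = {}
        for aa, codons in self.families.items():
            out.setdefault(len(codons), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in sorted(out.items())}

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, a in self.codon_to_aa.items() if a != STOP))

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """Codons in families of size >= 2 (the synonymously variable set)."""
        return tuple(
            sorted(
                c
                for aa, codons in self.families.items()
                if len(codons) >= 2
                for c in codons
            )
        )

    @property
    def fourfold_codons(self) -> tuple[str, ...]:
        """Codons in fourfold-degenerate boxes (third base free).

        A box is the four codons sharing the first two bases; it is fourfold
        degenerate when all four encode the same amino acid.  For the standard
        code these are the CTN, GTN, TCN, CCN, ACN, GCN, CGN and GGN boxes,
        which includes the fourfold sub-boxes of the sixfold Leu/Ser/Arg
        families.  This is the site set used by strict PR2 analysis.
        """
        out = []
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                box = [b1 + b2 + b3 for b3 in bases]
                aas = {self.codon_to_aa[c] for c in box}
                if len(aas) == 1 and STOP not in aas:
                    out.extend(box)
        return tuple(sorted(out))

    def family_of(self, codon: str) -> tuple[str, ...]:
        aa = self.codon_to_aa[to_dna(codon)]
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon; it has no family")
        return self.families[aa]


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    """Cached accessor for an NCBI genetic code table."""
    return GeneticCode.from_ncbi_id(table_id)


STANDARD_CODE = get_code(1)
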