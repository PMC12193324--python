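"""Reading genome records, CDS screening, and the cross-species shared set.

Mirrors the acquisition step of organelle codon-usage studies: parse a
GenBank (or multi-FASTA) file, pull out every annotated CDS with its spliced,
strand-corrected sequence, keep only translatable CDSs longer than 300 bp
that start with ATG and end with a canonical stop, collapse duplicate gene
copies to the longest, and intersect gene sets across species.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, get_code

logger = logging.getLogger(__name__)

VALID_STOPS = frozenset({"TGA", "TAA", "TAG"})
MIN_LENGTH_BP = 300  # screening keeps strictly greater than this
_COPY_SUFFIX = re.compile(r"[-_.](\d+|[a-z])$")


@dataclass
class CodingSequence:
    """One coding sequence: gene name, source species, nucleotides."""

    gene: str
    species: str
    nucleotides: str

    def __post_init__(self) -> None:
        self.nucleotides = self.nucleotides.upper()

    @property
    def length_bp(self) -> int:
        return len(self.nucleotides)

    @property
    def codons(self) -> list[str]:
        if self.length_bp % 3:
            raise ValueError(
                f"{self.gene}: length {self.length_bp} not divisible by 3"
            )
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]


@dataclass
class GenomeRecord:
    """A parsed genome with its raw (unscreened) CDS features."""

    accession: str
    species: str
    sequence_length: int
    cds_features: list[CodingSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")


def normalize_gene_name(name: str) -> str:
    """Lower-case and strip trailing copy suffixes ('nad5-1' -> 'nad5').

    GenBank annotations are inconsistent across records; matching shared
    genes across species needs a canonical form.
    """
    name = name.strip().lower()
    return _COPY_SUFFIX.sub("", name)


def _feature_gene_name(feature, index: int) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feature.qualifiers:
            if key != "gene":
                warnings.warn(
                    f"CDS feature #{index} lacks a gene qualifier; "
                    f"using {key}={feature.qualifiers[key][0]!r}"
                )
            return feature.qualifiers[key][0]
    warnings.warn(f"CDS feature #{index} has no name qualifiers; labeled cds{index}")
    return f"cds{index}"


def read_genbank(path: str | Path, species: str | None = None) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    Every CDS feature is extracted with its spliced, strand-corrected
    nucleotide sequence (multi-exon CDSs concatenated in coding order, as
    Biopython's ``feature.extract`` does). Coordinates in the file are
    1-based inclusive; in memory everything is a plain sequence string.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            record: SeqRecord = next(SeqIO.parse(fh, "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ValueError(f"{path} is not readable as GenBank: {exc}") from exc
    sp = species or record.annotations.get("organism", "") or record.id
    features = []
    idx = 0
    for feature in record.features:
        if feature.type != "CDS":
            continue
        idx += 1
        gene = _feature_gene_name(feature, idx)
        seq = str(feature.extract(record.seq))
        features.append(CodingSequence(gene=gene, species=sp, nucleotides=seq))
    return GenomeRecord(
        accession=record.id or record.name,
        species=sp,
        sequence_length=len(record.seq),
        cds_features=features,
    )


def read_fasta_cds(path: str | Path, species: str | None = None) -> GenomeRecord:
    """Read a multi-FASTA of CDSs as a :class:`GenomeRecord`.

    The record id is taken as the gene name (text after the first whitespace
    is ignored); sequence_length is the total bp across entries.
    """
    path = Path(path)
    feats = []
    total = 0
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            sp = species or "unknown"
            feats.append(
                CodingSequence(gene=rec.id, species=sp, nucleotides=str(rec.seq))
            )
            total += len(rec.seq)
    if not feats:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeRecord(
        accession=path.stem,
        species=species or "unknown",
        sequence_length=total,
        cds_features=feats,
    )


# -- screening ---------------------------------------------------------------


def _screen_one(
    cds: CodingSequence, code: GeneticCode, min_length_bp: int
) -> str | None:
    """Return None if the CDS passes, else the reason it fails."""
    n = cds.length_bp
    if n <= min_length_bp:
        return f"length {n} <= {min_length_bp}"
    if n % 3:
        return f"length {n} not divisible by 3"
    if set(cds.nucleotides) - set("ACGT"):
        return "ambiguity codes present"
    if cds.nucleotides[:3] != "ATG":
        return f"start codon {cds.nucleotides[:3]} != ATG"
    stop = cds.nucleotides[-3:]
    if stop not in VALID_STOPS:
        return f"stop codon {stop} not in TGA/TAA/TAG"
    internal = cds.codons[1:-1]
    if any(c in code.stop_codons for c in internal):
        return "internal stop codon"
    return None


def screen_cds(
    record: GenomeRecord,
    *,
    min_length_bp: int = MIN_LENGTH_BP,
    genetic_code: int = 1,
    manifest: list[dict] | None = None,
) -> list[CodingSequence]:
    """Apply the CDS screening rules and collapse duplicate gene copies.

    Keeps features with length strictly greater than ``min_length_bp``,
    length divisible by 3, ATG start, canonical stop, no ambiguity codes and
    no internal stops.  For duplicate (normalized) gene names only the
    longest copy is retained.  Output is sorted by gene name.

    If ``manifest`` is given, a dict per input feature (gene, species,
    length, outcome) is appended to it.
    """
    code = get_code(genetic_code)
    best: dict[str, CodingSequence] = {}
    for cds in record.cds_features:
        reason = _screen_one(cds, code, min_length_bp)
        name = normalize_gene_name(cds.gene)
        outcome = reason or "pass"
        if manifest is not None:
            manifest.append(
                {
                    "gene": name,
                    "species": cds.species,
                    "length_bp": cds.length_bp,
                    "outcome": outcome,
                }
            )
        if reason is not None:
            logger.info("screened out %s (%s): %s", cds.gene, cds.species, reason)
            continue
        kept = best.get(name)
        if kept is None or cds.length_bp > kept.length_bp:
            best[name] = CodingSequence(
                gene=name, species=cds.species, nucleotides=cds.nucleotides
            )
    return [best[k] for k in sorted(best)]


def shared_cds(
    per_species: list[list[CodingSequence]],
) -> dict[str, list[CodingSequence]]:
    """Genes present in every species list, as gene -> [one CDS per species].

    Gene names are matched after :func:`normalize_gene_name`.  An empty
    intersection returns an empty dict with a warning.
    """
    if len(per_species) < 2:
        raise ValueError("shared_cds needs at least two species lists")
    maps = []
    for lst in per_species:
        maps.append({normalize_gene_name(c.gene): c for c in lst})
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if not common:
        warnings.warn("no CDS shared across all species")
        return {}
    return {g: [m[g] for m in maps] for g in sorted(common)}


# -- writers -----------------------------------------------------------------


def write_fasta(cds_list: list[CodingSequence], path: str | Path) -> None:
    """Write CDSs to multi-FASTA (id = gene, description = species)."""
    records = [
        SeqRecord(Seq(c.nucleotides), id=c.gene, description=c.species)
        for c in cds_list
    ]
    SeqIO.write(records, str(path), "fasta")


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    """Write a screening manifest TSV (gene, species, length, outcome)."""
    import pandas as pd

    pd.DataFrame(manifest, columns=["gene", "species", "length_bp", "outcome"]).to_csv(
        path, sep="\t", index=False
    )
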