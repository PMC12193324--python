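"""Shared fixtures: worked example CDSs, random codon-count tables, and a
small GenBank file built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from mitocub import CodingSequence, get_code, worked_fixture
from mitocub.codon_metrics import CodonCounts

CODE = get_code(1)

# codons usable for building valid CDS bodies (no stops)
_BODY = ["AAA", "GCT", "CGA", "TGT", "GGC", "CTT", "TTC", "ACA"]


def make_cds(n_codons: int, start: str = "ATG", stop: str = "TAA") -> str:
    """A valid CDS of n_codons total codons with a repeating body."""
    body = [(_BODY[i % len(_BODY)]) for i in range(n_codons - 2)]
    return start + "".join(body) + stop


@pytest.fixture(scope="session")
def worked():
    """The hand-computed worked fixture: (cds list, expected value table)."""
    return worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_counts(rng: np.random.Generator, max_count: int = 50) -> CodonCounts:
    """A random codon count table over the sense codons (some zeros)."""
    counts = {}
    for codon in CODE.sense_codons:
        if rng.random() < 0.7:
            counts[codon] = int(rng.integers(0, max_count + 1))
    return CodonCounts({c: n for c, n in counts.items() if n > 0}, source="random")


# ---------------------------------------------------------------------------
# independent ENC oracle (first-principles, no package code)
# ---------------------------------------------------------------------------


def enc_brute_force(counts: dict[str, int]) -> float:
    """Wright's ENC computed independently from the definition.

    Same conventions as the implementation contract: families with n < 2
    skipped; class means over computed F values; class mean <= 0 treated as
    missing; missing class 3 imputed from classes 2 and 4; other missing
    classes dropped with ceiling renormalization; clip to [20, 61].
    """
    fam_by_aa: dict[str, list[str]] = {}
    for codon, aa in CODE.codon_to_aa.items():
        if aa != "*":
            fam_by_aa.setdefault(aa, []).append(codon)
    per_class_F: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    n_single = 0
    for aa, fam in fam_by_aa.items():
        k = len(fam)
        if k == 1:
            n_single += 1
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        ssq = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        per_class_F.setdefault(k, []).append((n * ssq - 1) / (n - 1))
    fbar = {}
    for k, fs in per_class_F.items():
        m = sum(fs) / len(fs)
        if m > 0:
            fbar[k] = m
    if 3 in class_sizes and 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if not fbar:
        return float("nan")
    enc = n_single + sum(class_sizes[k] / fbar[k] for k in fbar)
    missing = [k for k in class_sizes if k not in fbar]
    if missing:
        partial = n_single + sum(class_sizes[k] * k for k in fbar)
        full = n_single + sum(class_sizes[k] * k for k in class_sizes)
        enc *= full / partial
    return min(61.0, max(20.0, enc))


# ---------------------------------------------------------------------------
# GenBank fixture built at test time
# ---------------------------------------------------------------------------


@pytest.fixture()
def genbank_file(tmp_path):
    """A small GenBank file with forward/reverse/invalid/duplicate CDSs.

    Layout: atp1 (valid, 303 bp, forward), cob (valid, 306 bp, reverse
    strand), rps7 (250 bp, fails length), nad1 (GTG start), nad5 twice
    (600 bp and 900 bp, both valid).
    """
    pieces = {
        "atp1": (make_cds(101), +1),
        "cob": (make_cds(102), -1),
        "rps7": ("ATG" + "AAA" * 81 + "TAAA", +1),  # 250 bp
        "nad1": (make_cds(101, start="GTG"), +1),
        "nad5": (make_cds(200), +1),
        "nad5-2": (make_cds(300), +1),
    }
    genome = ""
    features = []
    for name, (seq, strand) in pieces.items():
        spacer = "ACGT" * 5
        genome += spacer
        start = len(genome)
        inserted = seq if strand == 1 else str(Seq(seq).reverse_complement())
        genome += inserted
        loc = FeatureLocation(start, start + len(inserted), strand=strand)
        features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": [name.split("-")[0] if name == "nad5-2" else name]})
        )
    # keep distinct qualifiers for the duplicate: both are "nad5"
    record = SeqRecord(
        Seq(genome),
        id="TEST0001",
        name="TEST0001",
        description="synthetic test genome",
        annotations={"organism": "Testus syntheticus", "molecule_type": "DNA"},
        features=features,
    )
    path = tmp_path / "test_genome.gb"
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")
    return path, pieces


@pytest.fixture(scope="session")
def trio_profiles():
    """Profiles + CDS lists for three small synthetic genomes (shared)."""
    from mitocub import SyntheticSpec, generate, profile_genes

    out = {}
    for i, sp in enumerate(["alpha", "beta", "gamma"]):
        cds, _ = generate(
            SyntheticSpec(n_genes=21, regime="mixed", seed=100 + i), species=sp
        )
        out[sp] = (cds, profile_genes(cds))
    return out
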