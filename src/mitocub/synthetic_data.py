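"""Synthetic CDS sets with known composition and selection ground truth.

The generator emulates the statistical structure that the downstream
diagnostics assume, so every pipeline stage can be tested without real
genomes:

* mutation regime — each gene draws a composition parameter θ uniformly
  from ``gc3_range`` and samples the G+C probability of *all three* codon
  positions from θ, so GC12 tracks GC3 across genes and the neutrality
  slope approaches 1.
* selection regime — the amino-acid sequence is random; codon choice mixes
  a preferred-codon set (probability ``selection_strength``) with
  third-position composition drawn from a per-gene parameter that is
  decoupled from positions 1–2, so the neutrality slope approaches 0.
* mixed — each gene is assigned one of the two regimes at random.

Every generated gene starts with ATG, ends with TAA, contains no internal
stop and has length in the configured codon range, so it passes the CDS
screen whenever the minimum length exceeds 300 bp.  Generation is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, get_code, to_dna
from .genome_io import CodingSequence

# The 21 CDSs shared by the three Medicago mitogenomes; reused as realistic
# gene names for synthetic sets (cycled, then numbered).
MEDICAGO_SHARED_GENES = (
    "atp1", "atp4", "atp8", "ccmb", "ccmc", "ccmfn", "cob", "cox1", "matr",
    "nad2", "nad3", "nad4", "nad5", "nad7", "nad9",
    "rpl16", "rpl5", "rps12", "rps14", "rps3", "rps4",
)

# Default preferred set for the selection regime: the 15 optimal codons
# shared by the three Medicago species (A/U-ending except UUG), as DNA.
DEFAULT_PREFERRED = frozenset(
    to_dna(c)
    for c in (
        "GCU", "UGU", "GAU", "GAA", "UUU", "CAU", "AAA", "CUU", "UUA",
        "UUG", "CAA", "UCA", "UCU", "ACA", "UAU",
    )
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic CDS set.

    ``codons_per_gene`` counts all codons including the ATG start and the
    stop; the default span (101–670 codons, i.e. 303–2010 bp) matches the
    size range of plant mitochondrial CDSs that survive the >300 bp screen.
    ``gc3_range`` defaults to the 0.28–0.58 span observed across the
    Medicago mitochondrial genes.  ``selection_strength`` 0 reduces the
    selection regime to pure composition sampling.
    """

    n_genes: int = 21
    codons_per_gene: tuple[int, int] = (101, 670)
    gc3_range: tuple[float, float] = (0.28, 0.58)
    regime: str = "mutation"  # mutation | selection | mixed
    preferred_codons: frozenset[str] = DEFAULT_PREFERRED
    selection_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        lo, hi = self.gc3_range
        if not (0 < lo <= hi < 1):
            raise ValueError("gc3_range must lie within (0, 1)")
        if self.regime not in ("mutation", "selection", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.selection_strength <= 1:
            raise ValueError("selection_strength must be in [0, 1]")
        if self.regime in ("selection", "mixed") and not self.preferred_codons:
            raise ValueError("selection regime needs a non-empty preferred set")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated CDS set."""

    regime: str
    per_gene: pd.DataFrame  # gene, regime, theta (composition parameter)
    preferred_codons: frozenset[str]
    expected_slope: float | None  # ~1 mutation, ~0 selection, None mixed
    seed: int


def _gene_names(n: int) -> list[str]:
    names = list(MEDICAGO_SHARED_GENES[:n])
    for i in range(len(names), n):
        names.append(f"gene{i + 1:03d}")
    return names


def _sample_composition_codons(
    rng: np.random.Generator, m: int, theta: float, stop_codons: frozenset[str]
) -> list[str]:
    """m interior codons, each base G/C with probability theta; no stops."""
    probs = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    out: list[str] = []
    need = m
    while need > 0:
        draw = rng.choice(4, size=(need, 3), p=probs)
        codons = ["".join(_BASES[row]) for row in draw]
        keep = [c for c in codons if c not in stop_codons]
        out.extend(keep)
        need = m - len(out)
    return out[:m]


def _selection_family_weights(
    fam: tuple[str, ...], phi: float
) -> np.ndarray:
    """Within-family codon weights from third-position composition phi."""
    w = np.array([phi / 2 if c[2] in "GC" else (1 - phi) / 2 for c in fam])
    return w / w.sum()


def _sample_selection_codons(
    rng: np.random.Generator,
    m: int,
    phi: float,
    strength: float,
    preferred_by_aa: dict[str, tuple[str, ...]],
    code: GeneticCode,
) -> list[str]:
    """m interior codons: preferred with prob ``strength``, else phi-weighted."""
    aas = sorted(code.families)
    aa_idx = rng.integers(0, len(aas), size=m)
    use_pref = rng.random(m) < strength
    out = np.empty(m, dtype=object)
    for k, aa in enumerate(aas):
        fam = code.families[aa]
        pos = np.where(aa_idx == k)[0]
        if pos.size == 0:
            continue
        pref = preferred_by_aa.get(aa)
        pref_pos = pos[use_pref[pos]] if pref else np.array([], dtype=int)
        comp_pos = np.setdiff1d(pos, pref_pos, assume_unique=True)
        if pref_pos.size:
            choice = rng.integers(0, len(pref), size=pref_pos.size)
            out[pref_pos] = np.array(pref, dtype=object)[choice]
        if comp_pos.size:
            w = _selection_family_weights(fam, phi)
            choice = rng.choice(len(fam), size=comp_pos.size, p=w)
            out[comp_pos] = np.array(fam, dtype=object)[choice]
    return list(out)


def generate(
    spec: SyntheticSpec, species: str = "synthetic"
) -> tuple[list[CodingSequence], SyntheticTruth]:
    """Generate a CDS set and its ground truth from a :class:`SyntheticSpec`."""
    rng = np.random.default_rng(spec.seed)
    code = get_code(1)
    names = _gene_names(spec.n_genes)
    preferred = frozenset(to_dna(c) for c in spec.preferred_codons)
    preferred_by_aa: dict[str, tuple[str, ...]] = {}
    for c in sorted(preferred):
        aa = code.codon_to_aa[c]
        if aa != "*":
            preferred_by_aa[aa] = preferred_by_aa.get(aa, ()) + (c,)

    lo, hi = spec.codons_per_gene
    rows = []
    cds_list = []
    for gene in names:
        if spec.regime == "mixed":
            regime = "mutation" if rng.random() < 0.5 else "selection"
        else:
            regime = spec.regime
        theta = float(rng.uniform(*spec.gc3_range))
        n_codons = int(rng.integers(lo, hi + 1))
        m = n_codons - 2  # interior codons between ATG and TAA
        if regime == "mutation":
            interior = _sample_composition_codons(rng, m, theta, code.stop_codons)
        else:
            interior = _sample_selection_codons(
                rng, m, theta, spec.selection_strength, preferred_by_aa, code
            )
        seq = "ATG" + "".join(interior) + "TAA"
        cds_list.append(CodingSequence(gene=gene, species=species, nucleotides=seq))
        rows.append({"gene": gene, "regime": regime, "theta": theta,
                     "n_codons": n_codons})

    expected = {"mutation": 1.0, "selection": 0.0}.get(spec.regime)
    truth = SyntheticTruth(
        regime=spec.regime,
        per_gene=pd.DataFrame(rows),
        preferred_codons=preferred,
        expected_slope=expected,
        seed=spec.seed,
    )
    return cds_list, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the per-gene ground-truth table as TSV."""
    df = truth.per_gene.copy()
    df["expected_slope"] = truth.expected_slope
    df["seed"] = truth.seed
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# worked fixture with hand-computed statistics
# ---------------------------------------------------------------------------


def worked_fixture() -> tuple[list[CodingSequence], dict]:
    """Tiny CDSs whose statistics were computed by hand from the definitions.

    Returns the sequences and a frozen table of expected values (codon
    counts, RSCU, positional GC with stop codons excluded, and ENC where the
    family homozygosities are exact).  Used as an independent oracle for the
    metric implementations.
    """
    seqs = {
        # ATG AAA AAG CGA CGA CGA TAA
        "F1": "ATGAAAAAGCGACGACGATAA",
        # uniform usage in Ala and Val families
        "F2": "ATG" + "GCTGCCGCAGCG" + "GTTGTCGTAGTG" + "TAA",
        # one codon per observed family, n=4 each -> every F-hat = 1, ENC = 20
        "F3": "ATG" + "AAA" * 4 + "GCT" * 4 + "CGA" * 4 + "ATT" * 4 + "GTT" * 4 + "TAA",
        # ATG GGG; GC3 convention: stop codon excluded
        "F4": "ATGGGGTAA",
    }
    expected = {
        "F1": {
            "counts": {"ATG": 1, "AAA": 1, "AAG": 1, "CGA": 3},
            "rscu": {"AAA": 1.0, "AAG": 1.0, "CGA": 6.0, "CGT": 0.0, "CGC": 0.0,
                     "CGG": 0.0, "AGA": 0.0, "AGG": 0.0, "ATG": 1.0},
            # 6 non-stop codons: ATG AAA AAG CGA CGA CGA
            "gc1": 50.0, "gc2": 50.0, "gc3": 100.0 / 3, "gc_all": 400.0 / 9,
            "gc12": 50.0,
            "a3": 4, "t3": 0, "c3": 0, "g3": 2,
            "gc3s": 20.0, "a3s": 0.8, "g3s": 0.2, "t3s": 0.0, "c3s": 0.0,
        },
        "F2": {
            "counts": {"ATG": 1, "GCT": 1, "GCC": 1, "GCA": 1, "GCG": 1,
                       "GTT": 1, "GTC": 1, "GTA": 1, "GTG": 1},
            "rscu": {c: 1.0 for c in
                     ("GCT", "GCC", "GCA", "GCG", "GTT", "GTC", "GTA", "GTG", "ATG")},
        },
        "F3": {
            "counts": {"ATG": 1, "AAA": 4, "GCT": 4, "CGA": 4, "ATT": 4, "GTT": 4},
            "enc": 20.0,
        },
        "F4": {
            "counts": {"ATG": 1, "GGG": 1},
            "gc1": 50.0, "gc2": 50.0, "gc3": 100.0, "gc_all": 200.0 / 3, "gc12": 50.0,
        },
    }
    cds = [
        CodingSequence(gene=g, species="fixture", nucleotides=s)
        for g, s in seqs.items()
    ]
    return cds, expected
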