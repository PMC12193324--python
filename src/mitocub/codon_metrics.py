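"""Per-gene and pooled codon usage statistics.

Implements the classic codon-usage index set on top of plain codon counts:

* RSCU — relative synonymous codon usage, the observed count of a codon
  divided by the mean count over its synonymous family (1 = no bias).
* ENC — Wright's effective number of codons, from per-family homozygosity
  averaged within degeneracy classes; 20 (one codon per amino acid) to 61
  (uniform usage, standard code).
* CAI — Sharp & Li's codon adaptation index, the geometric mean of relative
  adaptiveness weights over synonymously variable codons.
* CBI — Bennetzen & Hall's codon bias index, the excess of optimal codons
  over the random expectation, normalized to [-1, 1].
* Fop — Ikemura's frequency of optimal codons.
* Positional composition — GC1/GC2/GC3/GCall/GC12 and the synonymous
  third-position quantities GC3s and A3s/T3s/C3s/G3s.

The sklearn-style :class:`CodonUsageProfiler` turns a list of coding
sequences into a tidy per-gene index table; module-level functions expose
each statistic individually.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genetic_code import GeneticCode, get_code, to_dna
from .genome_io import CodingSequence

ENC_MIN = 20.0
ENC_MAX = 61.0
_CAI_WEIGHT_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# codon counting
# ---------------------------------------------------------------------------


@dataclass
class CodonCounts:
    """Codon -> count map for a gene or a pooled set of genes."""

    counts: dict[str, int]
    source: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        label = f"{self.source}+{other.source}" if self.source else other.source
        return CodonCounts(dict(merged), source=label)


def count_codons(
    cds: CodingSequence | str, include_stop: bool = False, *, genetic_code: int = 1
) -> CodonCounts:
    """Count consecutive non-overlapping triplets of a CDS.

    Stop codons are counted only when ``include_stop`` is set.  Raises on a
    length not divisible by 3.
    """
    if isinstance(cds, str):
        cds = CodingSequence(gene="seq", species="", nucleotides=cds)
    code = get_code(genetic_code)
    codons = cds.codons  # raises on frame error
    counts: Counter[str] = Counter()
    for c in codons:
        if c in code.stop_codons and not include_stop:
            continue
        counts[c] += 1
    return CodonCounts(dict(counts), source=cds.gene)


def pool_counts(counts_list: list[CodonCounts], source: str = "pool") -> CodonCounts:
    """Sum codon counts across genes (pooled, not per-gene averaged)."""
    merged: Counter[str] = Counter()
    for c in counts_list:
        merged.update(c.counts)
    return CodonCounts(dict(merged), source=source)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    RSCU(c) = x_c / (family total / family size).  Families with zero total
    are absent from the result (not zero-filled); single-codon families
    (Met, Trp in the standard code) get RSCU 1 when observed.  Stop codons
    are ignored.
    """
    code = code or get_code(1)
    out: dict[str, float] = {}
    for aa, fam in code.families.items():
        tot = sum(counts.counts.get(c, 0) for c in fam)
        if tot == 0:
            continue
        mean = tot / len(fam)
        for c in fam:
            out[c] = counts.counts.get(c, 0) / mean
    return out


def rscu_vector(
    counts: CodonCounts, code: GeneticCode | None = None, *, synonymous_only: bool = True
) -> pd.Series:
    """RSCU as a Series over the full codon universe (absent families NaN).

    ``synonymous_only`` restricts to families of size >= 2 (the 59-codon
    universe of the standard code), the usual input to RSCU clustering.
    """
    code = code or get_code(1)
    universe = code.synonymous_codons if synonymous_only else code.sense_codons
    vals = rscu(counts, code)
    return pd.Series({c: vals.get(c, np.nan) for c in universe}, name=counts.source)


# ---------------------------------------------------------------------------
# positional composition
# ---------------------------------------------------------------------------


@dataclass
class Composition:
    """Positional base composition of a codon set (percentages for GC*)."""

    n_codons: int
    gc1: float
    gc2: float
    gc3: float
    gc_all: float
    gc12: float
    gc3s: float  # NaN when no synonymous codons
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    a3: int
    t3: int
    c3: int
    g3: int


def third_position_counts(
    counts: CodonCounts, code: GeneticCode, *, fourfold_only: bool = False
) -> dict[str, int]:
    """Raw third-position base counts over synonymous (or fourfold) codons."""
    if fourfold_only:
        allowed = set(code.fourfold_codons)
    else:
        allowed = set(code.synonymous_codons)
    out = {"A": 0, "T": 0, "C": 0, "G": 0}
    for codon, n in counts.counts.items():
        if codon in allowed:
            out[codon[2]] += n
    return out


def composition(
    counts: CodonCounts | CodingSequence,
    code: GeneticCode | None = None,
    *,
    include_stop: bool = False,
) -> Composition:
    """Positional GC content and synonymous third-position base frequencies.

    GC1/GC2/GC3 are the percent G+C at each codon position over all counted
    codons (stops excluded unless ``include_stop``); GCall is their mean and
    GC12 the mean of the first two.  GC3s and A3s/T3s/C3s/G3s are computed
    over synonymously variable codons only (families of size >= 2, so Met,
    Trp and stops never contribute); with no synonymous codons they are NaN.
    """
    code = code or get_code(1)
    if isinstance(counts, CodingSequence):
        counts = count_codons(counts, include_stop=include_stop, genetic_code=code.table_id)
    n = 0
    gc_pos = [0, 0, 0]
    third = {"A": 0, "T": 0, "C": 0, "G": 0}
    syn = set(code.synonymous_codons)
    syn_third = {"A": 0, "T": 0, "C": 0, "G": 0}
    n_syn = 0
    for codon, x in counts.counts.items():
        codon = to_dna(codon)
        if codon in code.stop_codons and not include_stop:
            continue
        n += x
        for i in range(3):
            if codon[i] in "GC":
                gc_pos[i] += x
        third[codon[2]] += x
        if codon in syn:
            n_syn += x
            syn_third[codon[2]] += x
    if n == 0:
        raise ValueError("no codons to analyse")
    gc1, gc2, gc3 = (100.0 * g / n for g in gc_pos)
    if n_syn:
        syn_frac = {b: syn_third[b] / n_syn for b in "ATCG"}
        gc3s = 100.0 * (syn_frac["G"] + syn_frac["C"])
    else:
        syn_frac = {b: math.nan for b in "ATCG"}
        gc3s = math.nan
    return Composition(
        n_codons=n,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc_all=(gc1 + gc2 + gc3) / 3.0,
        gc12=(gc1 + gc2) / 2.0,
        gc3s=gc3s,
        a3s=syn_frac["A"],
        t3s=syn_frac["T"],
        c3s=syn_frac["C"],
        g3s=syn_frac["G"],
        a3=third["A"],
        t3=third["T"],
        c3=third["C"],
        g3=third["G"],
    )


# ---------------------------------------------------------------------------
# ENC (Wright)
# ---------------------------------------------------------------------------


def _family_homozygosity(counts: CodonCounts, fam: tuple[str, ...]) -> float | None:
    """Wright's estimated homozygosity F for one family; None if n < 2."""
    xs = [counts.counts.get(c, 0) for c in fam]
    n = sum(xs)
    if n < 2:
        return None
    s = sum((x / n) ** 2 for x in xs)
    return (n * s - 1.0) / (n - 1.0)


def enc_wright(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons.

    Per family with >= 2 counted codons, F = (n * sum p^2 - 1)/(n - 1);
    F values are averaged within each degeneracy class and

        ENC = 2 + N2/F2 + N3/F3 + N4/F4 + N6/F6

    with the class sizes of the active code (9/1/5/3 for the standard code;
    the leading 2 counts the single-codon amino acids).  A missing class-3
    average is imputed as the mean of the class-2 and class-4 averages
    (Wright 1990); any other missing class term is dropped and the partial
    sum rescaled so the uniform-usage ceiling stays at 61.  The result is
    clipped to [20, 61]; NaN when no family is computable.
    """
    code = code or get_code(1)
    class_F: dict[int, list[float]] = {}
    for aa, fam in code.families.items():
        if len(fam) < 2:
            continue
        F = _family_homozygosity(counts, fam)
        if F is not None:
            class_F.setdefault(len(fam), []).append(F)
    # class sizes in the code (number of families per degeneracy)
    class_sizes = {
        k: len(aas) for k, aas in code.degeneracy_classes.items() if k >= 2
    }
    n_single = len(code.degeneracy_classes.get(1, ()))
    Fbar: dict[int, float] = {}
    for k, Fs in class_F.items():
        m = float(np.mean(Fs))
        if m > 0:
            Fbar[k] = m
    if 3 in class_sizes and 3 not in Fbar and 2 in Fbar and 4 in Fbar:
        Fbar[3] = (Fbar[2] + Fbar[4]) / 2.0  # Wright's imputation for Ile
    if not Fbar:
        return math.nan
    enc = n_single + sum(class_sizes[k] / Fbar[k] for k in Fbar)
    missing = [k for k in class_sizes if k not in Fbar]
    if missing:
        # ceiling of the partial sum vs the full code's ceiling (61 standard)
        partial_max = n_single + sum(class_sizes[k] * k for k in Fbar)
        full_max = n_single + sum(class_sizes[k] * k for k in class_sizes)
        enc *= full_max / partial_max
    return float(min(ENC_MAX, max(ENC_MIN, enc)))


# ---------------------------------------------------------------------------
# reference sets and the reference-dependent indices
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """Optimal codons and CAI weights for the reference-dependent indices.

    CAI, CBI and Fop are all defined against a reference of highly expressed
    genes.  ``from_counts`` derives one from pooled codon counts (Sharp & Li:
    weight = RSCU / max family RSCU; optimal codon = family RSCU maximum).
    """

    name: str
    optimal_codons: frozenset[str]
    cai_weights: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, counts: CodonCounts, code: GeneticCode | None = None, name: str = "self"
    ) -> "ReferenceSet":
        code = code or get_code(1)
        vals = rscu(counts, code)
        weights: dict[str, float] = {}
        optimal: set[str] = set()
        for aa, fam in code.families.items():
            fam_vals = {c: vals.get(c, 0.0) for c in fam}
            top = max(fam_vals.values())
            if top <= 0:
                continue  # family unobserved in the reference pool
            for c, v in fam_vals.items():
                weights[c] = v / top
            if len(fam) >= 2:
                # ties broken alphabetically for determinism
                best = min(c for c, v in fam_vals.items() if v == top)
                optimal.add(best)
        return cls(name=name, optimal_codons=frozenset(optimal), cai_weights=weights)

    @classmethod
    def from_table(cls, weights: dict[str, float], code: GeneticCode | None = None,
                   name: str = "custom") -> "ReferenceSet":
        """Build from externally supplied codon -> weight values (DNA or RNA keys)."""
        code = code or get_code(1)
        w = {to_dna(c): float(v) for c, v in weights.items()}
        optimal: set[str] = set()
        for aa, fam in code.families.items():
            if len(fam) < 2:
                continue
            fam_w = {c: w.get(c, 0.0) for c in fam}
            top = max(fam_w.values())
            if top > 0:
                optimal.add(min(c for c, v in fam_w.items() if v == top))
        return cls(name=name, optimal_codons=frozenset(optimal), cai_weights=w)


def cai(counts: CodonCounts, ref: ReferenceSet, code: GeneticCode | None = None) -> float:
    """Codon adaptation index: geometric mean of reference weights.

    CAI = exp(sum x_c ln w_c / sum x_c) over synonymously variable codons
    (Met/Trp/stop excluded).  Observed codons with zero or missing weight
    are floored at 1e-4 with a warning.
    """
    code = code or get_code(1)
    syn = set(code.synonymous_codons)
    num = 0.0
    den = 0
    floored = []
    for codon, x in counts.counts.items():
        if codon not in syn or x == 0:
            continue
        w = ref.cai_weights.get(codon, 0.0)
        if w <= 0:
            floored.append(codon)
            w = _CAI_WEIGHT_FLOOR
        num += x * math.log(w)
        den += x
    if den == 0:
        return math.nan
    if floored:
        warnings.warn(
            f"CAI weights missing/zero for observed codons {sorted(floored)}; "
            f"floored at {_CAI_WEIGHT_FLOOR}"
        )
    return math.exp(num / den)


def _optimal_tallies(
    counts: CodonCounts, ref: ReferenceSet, code: GeneticCode
) -> tuple[float, float, float]:
    """(N_opt, N_ran, N_tot) over synonymously variable families."""
    n_opt = 0.0
    n_ran = 0.0
    n_tot = 0.0
    for aa, fam in code.families.items():
        if len(fam) < 2:
            continue
        fam_total = sum(counts.counts.get(c, 0) for c in fam)
        if fam_total == 0:
            continue
        k_opt = sum(1 for c in fam if c in ref.optimal_codons)
        n_tot += fam_total
        n_ran += fam_total * k_opt / len(fam)
        n_opt += sum(counts.counts.get(c, 0) for c in fam if c in ref.optimal_codons)
    return n_opt, n_ran, n_tot


def cbi(counts: CodonCounts, ref: ReferenceSet, code: GeneticCode | None = None) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran), in [-1, 1].

    N_ran is the optimal-codon count expected under uniform synonymous
    usage.  0 under exactly uniform usage, 1 when only optimal codons are
    used; NaN when the denominator is degenerate.
    """
    code = code or get_code(1)
    n_opt, n_ran, n_tot = _optimal_tallies(counts, ref, code)
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        return math.nan
    return (n_opt - n_ran) / (n_tot - n_ran)


def fop(counts: CodonCounts, ref: ReferenceSet, code: GeneticCode | None = None) -> float:
    """Frequency of optimal codons: N_opt / N_tot over synonymous codons."""
    code = code or get_code(1)
    n_opt, _, n_tot = _optimal_tallies(counts, ref, code)
    if n_tot == 0:
        return math.nan
    return n_opt / n_tot


# ---------------------------------------------------------------------------
# per-gene profile and the sklearn-style profiler
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = [
    "gene", "species", "n_codons", "enc", "cai", "cbi", "fop",
    "gc1", "gc2", "gc3", "gc_all", "gc12", "gc3s",
    "a3s", "t3s", "c3s", "g3s", "a3", "t3", "c3", "g3",
]


@dataclass
class GeneBiasProfile:
    """All per-gene codon usage indices for one coding sequence."""

    gene: str
    species: str
    n_codons: int
    enc: float
    cai: float
    cbi: float
    fop: float
    gc1: float
    gc2: float
    gc3: float
    gc_all: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    a3: int
    t3: int
    c3: int
    g3: int

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _as_cds_list(X) -> list[CodingSequence]:
    out = []
    for i, item in enumerate(X):
        if isinstance(item, CodingSequence):
            out.append(item)
        elif isinstance(item, (tuple, list)) and len(item) == 2:
            out.append(CodingSequence(gene=str(item[0]), species="", nucleotides=item[1]))
        elif isinstance(item, str):
            out.append(CodingSequence(gene=f"gene{i + 1}", species="", nucleotides=item))
        else:
            raise TypeError(
                "X must contain CodingSequence, (name, sequence) pairs, or strings"
            )
    if not out:
        raise ValueError("X is empty")
    return out


class CodonUsageProfiler(TransformerMixin, BaseEstimator):
    """Transform coding sequences into a per-gene codon-usage index table.

    Parameters
    ----------
    genetic_code : int, default 1
        NCBI translation table (1 = standard, used by land-plant mitochondria).
    reference : "self" or ReferenceSet, default "self"
        Reference for CAI/CBI/Fop.  ``"self"`` derives a Sharp–Li reference
        during :meth:`fit` from the pooled counts of the lowest-ENC decile of
        the fitted gene set (the putative high-expression pool).
    pool_fraction : float, default 0.10
        Fraction of genes (ceiling, minimum one) forming that pool.
    include_stop : bool, default False
        Count stop codons in GC1/GC2/GC3/GCall.  Stops never enter RSCU,
        ENC, CAI/CBI/Fop, GC3s or A3s..G3s.

    Attributes
    ----------
    reference_set_ : ReferenceSet
        The reference used for CAI/CBI/Fop.
    feature_names_out_ : list of str
        Columns of the transformed DataFrame.
    """

    def __init__(
        self,
        genetic_code: int = 1,
        reference: str | ReferenceSet = "self",
        pool_fraction: float = 0.10,
        include_stop: bool = False,
    ):
        self.genetic_code = genetic_code
        self.reference = reference
        self.pool_fraction = pool_fraction
        self.include_stop = include_stop

    def _code(self) -> GeneticCode:
        return get_code(self.genetic_code)

    def fit(self, X, y=None):
        cds_list = _as_cds_list(X)
        code = self._code()
        if isinstance(self.reference, ReferenceSet):
            self.reference_set_ = self.reference
        elif self.reference == "self":
            counts = [count_codons(c, genetic_code=code.table_id) for c in cds_list]
            encs = [(enc_wright(ct, code), c.gene, ct) for c, ct in zip(cds_list, counts)]
            encs.sort(key=lambda t: (math.isnan(t[0]), t[0], t[1]))
            k = max(1, math.ceil(self.pool_fraction * len(encs)))
            pooled = pool_counts([t[2] for t in encs[:k]], source="self-reference")
            self.reference_set_ = ReferenceSet.from_counts(pooled, code, name="self")
        else:
            raise ValueError(f"unknown reference {self.reference!r}")
        self.feature_names_out_ = list(PROFILE_COLUMNS)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "reference_set_"):
            raise ValueError("CodonUsageProfiler is not fitted; call fit first")
        cds_list = _as_cds_list(X)
        rows = [p.to_dict() for p in self.profiles(cds_list)]
        return pd.DataFrame(rows, columns=PROFILE_COLUMNS)

    def profiles(self, cds_list: list[CodingSequence]) -> list[GeneBiasProfile]:
        code = self._code()
        ref = self.reference_set_
        out = []
        for cds in cds_list:
            counts = count_codons(cds, genetic_code=code.table_id)
            comp = composition(
                count_codons(cds, include_stop=True, genetic_code=code.table_id)
                if self.include_stop
                else counts,
                code,
                include_stop=self.include_stop,
            )
            out.append(
                GeneBiasProfile(
                    gene=cds.gene,
                    species=cds.species,
                    n_codons=comp.n_codons,
                    enc=enc_wright(counts, code),
                    cai=cai(counts, ref, code),
                    cbi=cbi(counts, ref, code),
                    fop=fop(counts, ref, code),
                    gc1=comp.gc1, gc2=comp.gc2, gc3=comp.gc3,
                    gc_all=comp.gc_all, gc12=comp.gc12, gc3s=comp.gc3s,
                    a3s=comp.a3s, t3s=comp.t3s, c3s=comp.c3s, g3s=comp.g3s,
                    a3=comp.a3, t3=comp.t3, c3=comp.c3, g3=comp.g3,
                )
            )
        return out


def profile_genes(
    cds_list: list[CodingSequence],
    *,
    genetic_code: int = 1,
    reference: str | ReferenceSet = "self",
    pool_fraction: float = 0.10,
    include_stop: bool = False,
) -> pd.DataFrame:
    """One-call wrapper: fit a :class:`CodonUsageProfiler` and transform."""
    prof = CodonUsageProfiler(
        genetic_code=genetic_code,
        reference=reference,
        pool_fraction=pool_fraction,
        include_stop=include_stop,
    )
    return prof.fit(cds_list).transform(cds_list)
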