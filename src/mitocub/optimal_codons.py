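"""Optimal codon identification from ENC-ranked expression pools.

Genes are ranked by ENC; the lowest-ENC decile (strongest bias, putative
high expression) forms the high-expression pool and the highest-ENC decile
the low-expression pool.  RSCU is computed on pooled counts of each set
(RSCU-H, RSCU-L) and a codon is called optimal when RSCU-H > 1 (high
frequency) and ΔRSCU = RSCU-H − RSCU-L ≥ 0.08.  Single-codon families
(Met, Trp) are never callable: their RSCU is fixed at 1 and ΔRSCU at 0.

The package ships the published pool RSCU values and reported optimal-codon
calls for the mitochondrial genomes of *Medicago polymorpha* (MW971562),
*M. sativa* (ON782580) and *M. truncatula* (KT971339) as a plain-TSV
reference dataset (:func:`load_medicago_reference`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from sklearn.base import BaseEstimator

from .codon_metrics import (
    CodonCounts,
    count_codons,
    enc_wright,
    pool_counts,
    rscu,
)
from .genetic_code import GeneticCode, get_code, to_dna
from .genome_io import CodingSequence

DELTA_RSCU_THRESHOLD = 0.08
POOL_FRACTION = 0.10


@dataclass
class ExpressionPools:
    """High/low expression gene pools from the ENC ranking."""

    high_pool: list[str]  # lowest-ENC decile
    low_pool: list[str]  # highest-ENC decile
    pool_fraction: float


def build_pools(
    profiles: pd.DataFrame, fraction: float = POOL_FRACTION
) -> ExpressionPools:
    """Rank genes by ENC and take the extreme deciles.

    Pool size is ceil(fraction * N), minimum 1; ties in ENC break by gene
    name for determinism.  Raises if the fraction is outside (0, 0.5] or the
    two pools would overlap.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("pool fraction must be in (0, 0.5]")
    sub = profiles[["gene", "enc"]].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 genes with ENC to build pools")
    ranked = sub.sort_values(["enc", "gene"], kind="mergesort")
    k = max(1, math.ceil(fraction * len(ranked)))
    high = list(ranked["gene"].iloc[:k])
    low = list(ranked["gene"].iloc[-k:])
    if set(high) & set(low):
        raise ValueError(
            f"pool fraction {fraction} with {len(ranked)} genes makes the "
            "pools overlap"
        )
    return ExpressionPools(high_pool=high, low_pool=low, pool_fraction=fraction)


def pooled_rscu(
    counts_list: list[CodonCounts], code: GeneticCode | None = None, source: str = "pool"
) -> dict[str, float]:
    """RSCU of a gene pool: counts are summed first, then RSCU is taken."""
    if not counts_list:
        raise ValueError("empty pool")
    return rscu(pool_counts(counts_list, source=source), code or get_code(1))


@dataclass
class OptimalCodonReport:
    """Audit table and called optimal set for one genome.

    ``table`` has one row per codon with amino acid, RSCU-H, RSCU-L, ΔRSCU,
    the high-frequency flag (RSCU-H > 1) and the optimal call.
    """

    table: pd.DataFrame
    optimal_set: frozenset[str]
    delta_threshold: float

    @property
    def n_optimal(self) -> int:
        return len(self.optimal_set)


def call_optimal(
    rscu_high: dict[str, float],
    rscu_low: dict[str, float],
    *,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
    code: GeneticCode | None = None,
) -> OptimalCodonReport:
    """Apply the two optimal-codon criteria to pool RSCU tables.

    optimal ⇔ RSCU-H > 1 and (RSCU-H − RSCU-L) ≥ delta_threshold, over
    multi-codon families only.  Codons present in one table but missing from
    the other are treated as RSCU 0 with a warning.  Keys may be DNA or RNA;
    the report keeps the input spelling of the high table.
    """
    code = code or get_code(1)
    high = {to_dna(c): v for c, v in rscu_high.items()}
    low = {to_dna(c): v for c, v in rscu_low.items()}
    spelling = {to_dna(c): c for c in rscu_high}
    spelling.update({to_dna(c): c for c in rscu_low if to_dna(c) not in spelling})
    missing = (set(high) - set(low)) | (set(low) - set(high))
    if missing:
        warnings.warn(
            f"codons missing from one pool table treated as RSCU 0: {sorted(missing)}"
        )
    rows = []
    for codon in sorted(set(high) | set(low)):
        aa = code.codon_to_aa.get(codon)
        if aa is None or aa == "*":
            continue
        h = high.get(codon, 0.0)
        lo = low.get(codon, 0.0)
        delta = h - lo
        callable_fam = len(code.families[aa]) >= 2
        high_freq = h > 1.0
        rows.append(
            {
                "amino_acid": aa,
                "codon": spelling[codon],
                "rscu_high": h,
                "rscu_low": lo,
                "delta_rscu": delta,
                "high_frequency": high_freq,
                "optimal": callable_fam and high_freq and delta >= delta_threshold,
            }
        )
    table = pd.DataFrame(rows).sort_values(["amino_acid", "codon"]).reset_index(drop=True)
    optimal = frozenset(table.loc[table["optimal"], "codon"])
    return OptimalCodonReport(
        table=table, optimal_set=optimal, delta_threshold=delta_threshold
    )


def shared_optimal(sets: list[frozenset[str] | set[str]]) -> dict:
    """Intersect per-species optimal codon sets and tally codon endings.

    Returns the shared set plus counts of A/U-ending and G/C-ending codons.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 optimal sets")
    shared = set(sets[0])
    for s in sets[1:]:
        shared &= set(s)
    au = sorted(c for c in shared if c[-1].upper() in "ATU")
    gc = sorted(c for c in shared if c[-1].upper() in "GC")
    return {
        "shared": frozenset(shared),
        "n_shared": len(shared),
        "au_ending": au,
        "gc_ending": gc,
        "n_au_ending": len(au),
        "n_gc_ending": len(gc),
    }


class OptimalCodonFinder(BaseEstimator):
    """End-to-end optimal-codon caller for one genome's CDS set.

    ``fit(X)`` takes coding sequences (as accepted by
    :class:`~mitocub.codon_metrics.CodonUsageProfiler`), ranks them by ENC,
    pools the extreme deciles, and calls optimal codons.

    Attributes
    ----------
    pools_ : ExpressionPools
    report_ : OptimalCodonReport
    optimal_codons_ : frozenset of str
    """

    def __init__(
        self,
        pool_fraction: float = POOL_FRACTION,
        delta_threshold: float = DELTA_RSCU_THRESHOLD,
        genetic_code: int = 1,
    ):
        self.pool_fraction = pool_fraction
        self.delta_threshold = delta_threshold
        self.genetic_code = genetic_code

    def fit(self, X, y=None):
        from .codon_metrics import _as_cds_list  # shared input validation

        cds_list = _as_cds_list(X)
        code = get_code(self.genetic_code)
        counts = {
            c.gene: count_codons(c, genetic_code=code.table_id) for c in cds_list
        }
        profiles = pd.DataFrame(
            {
                "gene": list(counts),
                "enc": [enc_wright(ct, code) for ct in counts.values()],
            }
        )
        self.pools_ = build_pools(profiles, self.pool_fraction)
        rscu_h = pooled_rscu(
            [counts[g] for g in self.pools_.high_pool], code, source="high"
        )
        rscu_l = pooled_rscu(
            [counts[g] for g in self.pools_.low_pool], code, source="low"
        )
        self.report_ = call_optimal(
            rscu_h, rscu_l, delta_threshold=self.delta_threshold, code=code
        )
        self.optimal_codons_ = self.report_.optimal_set
        return self


def find_optimal_codons(
    cds_list: list[CodingSequence],
    *,
    pool_fraction: float = POOL_FRACTION,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
    genetic_code: int = 1,
) -> OptimalCodonReport:
    """Functional wrapper over :class:`OptimalCodonFinder`."""
    finder = OptimalCodonFinder(
        pool_fraction=pool_fraction,
        delta_threshold=delta_threshold,
        genetic_code=genetic_code,
    ).fit(cds_list)
    return finder.report_


# ---------------------------------------------------------------------------
# published Medicago reference dataset
# ---------------------------------------------------------------------------


def load_medicago_reference() -> pd.DataFrame:
    """Published pool RSCU values for three Medicago mitochondrial genomes.

    Columns: species, amino_acid, codon (RNA spelling), rscu_high, rscu_low,
    delta_printed (ΔRSCU as published, which for four *M. polymorpha* rows
    differs from rscu_high − rscu_low of the same rows), reported_optimal
    (the published optimal-codon call).
    """
    with resources.files("mitocub.data").joinpath(
        "medicago_mito_rscu_pools.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["reported_optimal"] = df["reported_optimal"].astype(bool)
    return df
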