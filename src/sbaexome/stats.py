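"""Exact cohort statistics: contingency tables, burdens, genes, pathways.

All exact tests use the minimum-likelihood two-sided convention (the sum of
outcome probabilities no larger than the observed one), which is what R's
``fisher.test`` and ``binom.test`` report. The 2x2 odds-ratio estimate is
the conditional maximum-likelihood estimate under the noncentral
hypergeometric model, with a 95% CI from inverting the exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from sbaexome.mmr import SampleProfile
from sbaexome.variants import VariantCall

# relative slack when comparing table probabilities, as in R's fisher.test
_REL_EPS = 1e-7


@dataclass
class ContingencyTable:
    counts: np.ndarray  # 2 x K
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2 or self.counts.shape[1] < 2:
            raise ValueError("table must be 2 x K with K >= 2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.col_labels:
            self.col_labels = tuple(f"col{i + 1}" for i in range(self.counts.shape[1]))


@dataclass
class ExactTestResult:
    statistic_name: str
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float


def fisher_exact_2x2(table: ContingencyTable | Sequence[Sequence[int]]) -> ExactTestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided P sums hypergeometric point probabilities <= the observed
    one; the estimate is the conditional-MLE odds ratio with an exact 95%
    CI. A zero cell yields an estimate of 0 or inf with the corresponding
    one-sided CI endpoint.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin; odds ratio undefined")
    p = sps.fisher_exact(counts, alternative="two-sided")[1]
    orr = sps.contingency.odds_ratio(counts, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return ExactTestResult(
        statistic_name="conditional MLE odds ratio",
        estimate=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(min(p, 1.0)),
    )


def _log_table_prob(row1: np.ndarray, col_totals: np.ndarray, n: int, n1: int) -> float:
    # P(table | margins) = prod_j C(col_j, a_j) / C(n, n1)
    return float(
        sum(
            gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
            for a, c in zip(row1, col_totals)
        )
        - (gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1))
    )


def fisher_exact_2xk(
    table: ContingencyTable | Sequence[Sequence[int]],
    enumeration_bound: int = 500,
    method: str = "exact",
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> ExactTestResult:
    """Exact (or Monte Carlo) test of independence for a 2xK table.

    The exact P enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table (no
    estimate or CI is defined for K > 2). Totals above
    ``enumeration_bound`` must use ``method='monte_carlo'``, a seeded
    fixed-margin sampler.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("fisher_exact_2xk requires a 2 x K table")
    col_totals = counts.sum(axis=0)
    n = int(counts.sum())
    n1 = int(counts[0].sum())
    k = counts.shape[1]
    log_p_obs = _log_table_prob(counts[0], col_totals, n, n1)
    threshold = log_p_obs + np.log1p(_REL_EPS)

    if method == "exact":
        if n > enumeration_bound:
            raise ValueError(
                f"table total {n} exceeds enumeration bound {enumeration_bound}; "
                "use method='monte_carlo'"
            )
        total = 0.0

        def recurse(j: int, remaining: int, log_acc: float) -> None:
            nonlocal total
            if j == k - 1:
                a = remaining
                if 0 <= a <= col_totals[j]:
                    lp = log_acc + (
                        gammaln(col_totals[j] + 1) - gammaln(a + 1) - gammaln(col_totals[j] - a + 1)
                    )
                    lp -= gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1)
                    if lp <= threshold:
                        total += np.exp(lp)
                return
            hi = min(col_totals[j], remaining)
            for a in range(hi + 1):
                lc = gammaln(col_totals[j] + 1) - gammaln(a + 1) - gammaln(col_totals[j] - a + 1)
                recurse(j + 1, remaining - a, log_acc + lc)

        recurse(0, n1, 0.0)
        p = min(total, 1.0)
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        hits = 0
        # sample row-1 cell counts from the multivariate hypergeometric with
        # the observed margins
        for _ in range(n_monte_carlo):
            draw = rng.multivariate_hypergeometric(col_totals, n1)
            if _log_table_prob(draw, col_totals, n, n1) <= threshold:
                hits += 1
        p = (hits + 1) / (n_monte_carlo + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ExactTestResult("2xK exact test", None, None, None, float(p))


def exact_binomial(x: int, n: int, p0: float) -> ExactTestResult:
    """Two-sided exact binomial test (minimum-likelihood convention).

    P = sum of Binomial(n, p0) point probabilities no larger than that of
    the observed count x; the estimate is the sample proportion with a
    Clopper-Pearson 95% CI.
    """
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0,1]")
    res = sps.binomtest(x, n, p0, alternative="two-sided")
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return ExactTestResult(
        statistic_name="proportion",
        estimate=x / n if n else float("nan"),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
    )


# --- descriptive cohort tables ------------------------------------------------

def mutation_burden_table(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    class_labels: Mapping[str, str],
    target_mb: float,
) -> pd.DataFrame:
    """Per-class median and IQR of mutation counts by consequence and mut/Mb."""
    rows = []
    for sample, calls in calls_by_sample.items():
        counts = {
            "total": len(calls),
            "non_synonymous": sum(c.is_nonsynonymous for c in calls),
            "missense": sum(c.consequence == "missense" for c in calls),
            "nonsense": sum(c.consequence == "nonsense" for c in calls),
            "frameshift": sum(c.consequence == "frameshift" for c in calls),
            "mut_per_mb": len(calls) / target_mb,
        }
        counts["sample_id"] = sample
        counts["mmr_class"] = class_labels.get(sample, "NA")
        rows.append(counts)
    df = pd.DataFrame(rows)
    out = []
    for cls, grp in df.groupby("mmr_class"):
        for col in ["total", "non_synonymous", "missense", "nonsense", "frameshift", "mut_per_mb"]:
            out.append(
                {
                    "mmr_class": cls,
                    "quantity": col,
                    "median": float(grp[col].median()),
                    "iqr_low": float(grp[col].quantile(0.25)),
                    "iqr_high": float(grp[col].quantile(0.75)),
                }
            )
    return pd.DataFrame(out)


def gene_frequency_table(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    class_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fraction of samples carrying >=1 non-synonymous mutation per gene.

    A sample counts once per gene regardless of mutation multiplicity;
    synonymous/UTR/other consequences never count.
    """
    class_labels = class_labels or {}
    hits: dict[tuple[str, str], set[str]] = {}
    class_sizes: dict[str, set[str]] = {}
    for sample, calls in calls_by_sample.items():
        cls = class_labels.get(sample, "all")
        class_sizes.setdefault(cls, set()).add(sample)
        for c in calls:
            if c.gene and c.is_nonsynonymous:
                hits.setdefault((c.gene, cls), set()).add(sample)
    rows = [
        {
            "gene": gene,
            "mmr_class": cls,
            "n_mutated": len(samples),
            "n_samples": len(class_sizes[cls]),
            "fraction": len(samples) / len(class_sizes[cls]),
        }
        for (gene, cls), samples in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "mmr_class", "n_mutated", "n_samples", "fraction"])


def _parse_protein_change(pc: str) -> tuple[str, int, str] | None:
    pc = pc.removeprefix("p.")
    if len(pc) < 3 or not pc[0].isalpha():
        return None
    i = 1
    while i < len(pc) and pc[i].isdigit():
        i += 1
    if i == 1 or i == len(pc):
        return None
    try:
        return pc[0], int(pc[1:i]), pc[i:]
    except ValueError:
        return None


def hotspot_table(calls: Iterable[VariantCall], min_samples: int = 2) -> pd.DataFrame:
    """Recurrently mutated protein positions (>= ``min_samples`` samples).

    Alternate residues at one position are grouped, e.g. D594A/G/N.
    Unparseable protein changes are skipped (count returned separately via
    attrs['n_unparsed']).
    """
    seen: dict[tuple[str | None, int, str], dict[str, set[str]]] = {}
    n_unparsed = 0
    for c in calls:
        if not c.protein_change:
            continue
        parsed = _parse_protein_change(c.protein_change)
        if parsed is None:
            n_unparsed += 1
            continue
        ref_aa, position, alt_aa = parsed
        slot = seen.setdefault((c.gene, position, ref_aa), {})
        slot.setdefault(alt_aa, set()).add(c.sample_id)
    rows = []
    for (gene, position, ref_aa), alts in sorted(seen.items(), key=lambda t: (t[0][0] or "", t[0][1])):
        samples = set().union(*alts.values())
        if len(samples) < min_samples:
            continue
        alt_order = sorted(alts)
        rows.append(
            {
                "gene": gene,
                "position": position,
                "label": f"{ref_aa}{position}{'/'.join(alt_order)}",
                "n_samples": len(samples),
                "alt_residues": ",".join(alt_order),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "position", "label", "n_samples", "alt_residues"])
    df.attrs["n_unparsed"] = n_unparsed
    return df


def pathway_frequency(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    pathway_map: Mapping[str, Sequence[str]],
    class_labels: Mapping[str, str] | None = None,
    class_filter: str | None = None,
) -> pd.DataFrame:
    """Fraction of samples with >=1 non-synonymous mutation in each pathway.

    ``pathway_map`` maps gene symbol -> list of pathway names. A sample is
    pathway-mutated when any member gene carries a non-synonymous mutation;
    multiple mutated genes in the same pathway still count the sample once.
    """
    class_labels = class_labels or {}
    samples = [
        s
        for s in calls_by_sample
        if class_filter is None or class_labels.get(s) == class_filter
    ]
    pathway_hits: dict[str, set[str]] = {}
    for sample in samples:
        for c in calls_by_sample[sample]:
            if c.gene and c.is_nonsynonymous:
                for pw in pathway_map.get(c.gene, ()):
                    pathway_hits.setdefault(pw, set()).add(sample)
    rows = [
        {
            "pathway": pw,
            "n_mutated": len(hit),
            "n_samples": len(samples),
            "fraction": len(hit) / len(samples) if samples else 0.0,
        }
        for pw, hit in sorted(pathway_hits.items())
    ]
    return pd.DataFrame(rows, columns=["pathway", "n_mutated", "n_samples", "fraction"])


def burden_medians(profiles: Iterable[SampleProfile]) -> pd.DataFrame:
    """Median/IQR of mut/Mb burden per MMR class from sample profiles."""
    df = pd.DataFrame(
        [{"mmr_class": p.mmr_class, "burden": p.burden} for p in profiles]
    )
    rows = []
    for cls, grp in df.groupby("mmr_class"):
        rows.append(
            {
                "mmr_class": cls,
                "median_burden": float(grp["burden"].median()),
                "iqr_low": float(grp["burden"].quantile(0.25)),
                "iqr_high": float(grp["burden"].quantile(0.75)),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)
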