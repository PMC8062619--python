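"""Differential expression and the clinical efficacy test.

Three comparisons mirror the study design:

* paired pre vs post treatment, per gene, on within-patient differences of
  log2 expression (two-tailed paired t);
* unpaired pre-treatment comparisons — complete vs incomplete responders
  (CR vs IR) and adverse-event vs no-adverse-event — with Welch's t
  (unequal variances, small unequal groups);
* the clinical efficacy test: paired t of the maximum lesion count during
  treatment (Lmax) against the week-14 count.

All gene-level p-values receive Benjamini-Hochberg FDR adjustment across the
tested genes. Genes zeroed by the detection-limit filter carry no variance
and are excluded from testing (reported as untested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizedMatrix
from .synthetic import SampleAnnotation

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised when the sample design cannot support the requested test."""


@dataclass(frozen=True)
class TestResult:
    """A single paired t-test outcome."""

    statistic: float
    p_value: float
    df: int
    tails: str = "two"


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(
    genes: list[str], lfc: np.ndarray, t: np.ndarray, p: np.ndarray, untested: Sequence[str]
) -> pd.DataFrame:
    adj = bh_adjust(p)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": lfc,
            "t": t,
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(lfc > 0, "up", "down"),
        }
    ).set_index("gene_id")
    df.attrs["untested"] = tuple(untested)
    return df


def _tested_genes(
    norm: NormalizedMatrix, genes: Sequence[str] | None
) -> tuple[list[str], list[str]]:
    pool = list(genes) if genes is not None else norm.genes
    pool = [g for g in pool if g in norm.values.index]
    tested = [g for g in pool if g not in norm.lod_zeroed]
    untested = [g for g in pool if g in norm.lod_zeroed]
    if untested:
        logger.info("%d genes below detection limit excluded from testing", len(untested))
    return tested, untested


def paired_de(
    norm: NormalizedMatrix,
    annotations: Sequence[SampleAnnotation],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene paired t-test of post vs pre treatment log2 expression.

    Only patients with both a pre and a post sample contribute; log2fc is
    the mean within-patient (post - pre) difference. Genes with identically
    zero differences get p = 1. ``genes`` restricts testing (e.g. to the
    measured panel genes, excluding control probes); default is every row.
    """
    by_patient: dict[str, dict[str, str]] = {}
    for a in annotations:
        if a.sample_id in norm.values.columns:
            by_patient.setdefault(a.patient_id, {})[a.timepoint] = a.sample_id
    matched = sorted(p for p, tps in by_patient.items() if {"pre", "post"} <= set(tps))
    if len(matched) < 2:
        raise DesignError(f"need >=2 matched pre/post pairs, found {len(matched)}")
    pre_cols = [by_patient[p]["pre"] for p in matched]
    post_cols = [by_patient[p]["post"] for p in matched]

    X = norm.log_values()
    tested, untested = _tested_genes(norm, genes)
    diffs = X.loc[tested, post_cols].to_numpy() - X.loc[tested, pre_cols].to_numpy()
    lfc = diffs.mean(axis=1)
    n = diffs.shape[1]
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf), t)
    p = np.where(zero_var, np.where(lfc == 0, 1.0, 0.0), p)
    return _finalize(tested, lfc, t, p, untested)


def group_de(
    norm: NormalizedMatrix,
    annotations: Sequence[SampleAnnotation],
    grouping: str = "response",
    timepoint: str = "pre",
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two pre-treatment groups.

    ``grouping='response'`` compares CR against IR (log2fc = CR - IR);
    ``grouping='adverse_event'`` compares AE against no-AE (log2fc =
    AE - no AE). Results are sorted by p-value.
    """
    if grouping == "response":
        split = {"CR": [], "IR": []}
        for a in annotations:
            if a.timepoint == timepoint and a.response in split:
                split[a.response].append(a.sample_id)
        g2_cols, g1_cols = split["CR"], split["IR"]
    elif grouping == "adverse_event":
        split = {"yes": [], "no": []}
        for a in annotations:
            if a.timepoint == timepoint and a.adverse_event in split:
                split[a.adverse_event].append(a.sample_id)
        g2_cols, g1_cols = split["yes"], split["no"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    g1_cols = [s for s in g1_cols if s in norm.values.columns]
    g2_cols = [s for s in g2_cols if s in norm.values.columns]
    if min(len(g1_cols), len(g2_cols)) < 2:
        raise DesignError(
            f"{grouping}: need >=2 samples per group, found {len(g2_cols)} vs {len(g1_cols)}"
        )

    X = norm.log_values()
    tested, untested = _tested_genes(norm, genes)
    a = X.loc[tested, g2_cols].to_numpy()
    b = X.loc[tested, g1_cols].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf), t)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    result = _finalize(tested, lfc, t, p, untested)
    return result.sort_values(["p_value", "gene_id"], kind="mergesort")


def de_count_enrichment(n_significant: int, n_total: int, alpha: float) -> float:
    """Exact tail probability of observing >= n_significant hits by chance.

    Under the null every gene is significant independently with probability
    ``alpha``, so the tail is P(X >= n_significant) for
    X ~ Binomial(n_total, alpha).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total")
    return float(stats.binom.sf(n_significant - 1, n_total, alpha))


def lesion_reduction_test(
    lmax: Sequence[int], week14: Sequence[int]
) -> TestResult:
    """Two-tailed paired t comparing Lmax with the week-14 lesion count."""
    x = np.asarray(lmax, dtype=float)
    y = np.asarray(week14, dtype=float)
    if x.shape != y.shape:
        raise DesignError("lmax and week14 must have equal length")
    if x.size < 2:
        raise DesignError("need >=2 patients")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(statistic=0.0, p_value=1.0, df=n - 1)
        return TestResult(statistic=float(np.sign(d.mean()) * np.inf), p_value=0.0, df=n - 1)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(statistic=float(t), p_value=float(p), df=n - 1)


def lesion_reduction_from_annotations(
    annotations: Sequence[SampleAnnotation],
) -> TestResult:
    """Efficacy test from sample annotations (one row per unique patient)."""
    per_patient: dict[str, tuple[int, int]] = {}
    for a in annotations:
        per_patient[a.patient_id] = (a.lesion_count_lmax, a.lesion_count_week14)
    patients = sorted(per_patient)
    lmax = [per_patient[p][0] for p in patients]
    week14 = [per_patient[p][1] for p in patients]
    return lesion_reduction_test(lmax, week14)
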