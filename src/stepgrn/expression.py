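"""Differential expression across the two transformation steps.

The three-stage isogenic design is compared as stage2-vs-stage1 (step 1,
immortalization) and stage3-vs-stage1 (step 2, oncogene-induced
transformation).  A gene is a DEG when, in at least one step, its linear
fold ratio exceeds the fold gate (>2 or <0.5) and its per-step p-value from
an unequal-variance t-test on log2 values clears the significance gate
(p < 0.05).  DEGs are then classified into seven co-expression pathways by
the pattern of their per-step up/down/ns calls.

With only two biological replicates per stage a plain Welch t-test is
essentially powerless (its Satterthwaite degrees of freedom hover near 2),
so the default DEG test moderates the per-group variances toward a common
prior estimated across genes, in the spirit of the regularized t-statistics
standard for replicate-starved expression designs.  Setting
``var_prior_df=0`` recovers the plain Welch test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DEFAULT_PATTERN_MAPPING,
    DEFAULT_STAGES,
    NO_PATHWAY,
    ConfigurationError,
)
from .io import ExpressionMatrix

log = logging.getLogger("stepgrn.degs")

CALLS = ("up", "down", "ns")


def welch_t(x, y):
    """Two-sample unequal-variance t-test (Welch).

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.  Antisymmetric in argument order: swapping ``x`` and
    ``y`` flips the sign of ``t`` and leaves ``df`` and ``p`` unchanged.
    If both samples have zero variance and equal means the test is undefined
    and ``(0, inf, 1)`` is returned by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("welch_t requires at least 2 values per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0.0 and vy == 0.0:
        if dm == 0.0:
            return 0.0, np.inf, 1.0
        return np.sign(dm) * np.inf, np.inf, 0.0
    sx = vx / x.size
    sy = vy / y.size
    se = np.sqrt(sx + sy)
    t = dm / se
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _moderated_welch(x: np.ndarray, y: np.ndarray, prior_df: float):
    """Vectorized Welch t over genes with variance moderation.

    ``x``/``y`` are gene x replicate arrays.  Per-group sample variances are
    shrunk toward a prior (the mean per-gene variance of that group across
    all genes) with ``prior_df`` pseudo-degrees of freedom; group degrees of
    freedom are augmented accordingly before Welch-Satterthwaite combination.
    ``prior_df == 0`` is the plain Welch test.
    """
    nx, ny = x.shape[1], y.shape[1]
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    if prior_df > 0:
        prior_x = float(vx.mean())
        prior_y = float(vy.mean())
        dfx = prior_df + (nx - 1)
        dfy = prior_df + (ny - 1)
        vx = (prior_df * prior_x + (nx - 1) * vx) / dfx
        vy = (prior_df * prior_y + (ny - 1) * vy) / dfy
    else:
        dfx, dfy = nx - 1, ny - 1
    sx = vx / nx
    sy = vy / ny
    se2 = sx + sy
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / (sx**2 / dfx + sy**2 / dfy)
    zero = se2 == 0.0
    t = np.where(zero, 0.0, t)
    df = np.where(zero, np.inf, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero & (t == 0.0), 1.0, p)
    return t, df, p


def call_degs(
    matrix: ExpressionMatrix,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    stages=DEFAULT_STAGES,
    var_prior_df: float = 8.0,
    bh_correct: bool = False,
    pattern_mapping=DEFAULT_PATTERN_MAPPING,
) -> pd.DataFrame:
    """Per-gene fold ratios, p-values, up/down/ns calls, and pathway labels.

    Fold ratios are computed from replicate means on the linear scale; tests
    run on log2 values.  ``call == up`` iff ratio > fc_up and p < alpha;
    ``down`` iff ratio < fc_down and p < alpha; otherwise ``ns``.  A gene is
    a DEG iff at least one step call is non-ns, and each DEG receives one of
    the seven pathway labels from ``pattern_mapping``.
    """
    matrix.validate(stages)
    baseline, *steps = stages
    if len(steps) != 2:
        raise ConfigurationError("expected a baseline stage plus two steps")
    base_lin = matrix.stage_values(baseline)
    base_log = np.log2(base_lin + 1e-9)
    table = pd.DataFrame(index=matrix.values.index.copy())

    for k, stage in enumerate(steps, start=1):
        stage_lin = matrix.stage_values(stage)
        ratio = stage_lin.mean(axis=1) / np.maximum(base_lin.mean(axis=1), 1e-12)
        t, df, p = _moderated_welch(np.log2(stage_lin + 1e-9), base_log, var_prior_df)
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            p = multipletests(p, method="fdr_bh")[1]
        call = np.where(
            (ratio > fc_up) & (p < alpha), "up",
            np.where((ratio < fc_down) & (p < alpha), "down", "ns"),
        )
        table[f"ratio_step{k}"] = ratio
        table[f"t_step{k}"] = t
        table[f"p_step{k}"] = p
        table[f"call_step{k}"] = call

    return assign_pathways(table, pattern_mapping)


def assign_pathways(table: pd.DataFrame, mapping=DEFAULT_PATTERN_MAPPING) -> pd.DataFrame:
    """Attach a pathway label to every DEG from its (call_step1, call_step2).

    ``mapping`` must cover all 8 non-(ns,ns) patterns; the default merges the
    two discordant-reversal patterns so 8 patterns map onto 7 labels.
    Non-DEGs get the ``none`` label.
    """
    required = {
        (a, b) for a in CALLS for b in CALLS if (a, b) != ("ns", "ns")
    }
    missing = required - set(mapping)
    if missing:
        raise ConfigurationError(f"pattern mapping misses patterns: {sorted(missing)}")
    table = table.copy()
    labels = []
    for a, b in zip(table["call_step1"], table["call_step2"]):
        labels.append(NO_PATHWAY if (a, b) == ("ns", "ns") else mapping[(a, b)])
    table["pathway"] = labels
    return table


def pathway_summary(table: pd.DataFrame) -> dict[str, float]:
    """Fractions of DEGs changed at step 1, at step 2, and at both.

    Satisfies the inclusion-exclusion identity
    ``frac_step1 + frac_step2 - frac_both == 1`` over the DEG set.
    """
    degs = table[table["pathway"] != NO_PATHWAY]
    if len(degs) == 0:
        log.warning("pathway_summary: empty DEG set, fractions undefined")
        return {"frac_step1": np.nan, "frac_step2": np.nan, "frac_both": np.nan,
                "n_degs": 0}
    s1 = degs["call_step1"] != "ns"
    s2 = degs["call_step2"] != "ns"
    n = float(len(degs))
    return {
        "frac_step1": float(s1.sum()) / n,
        "frac_step2": float(s2.sum()) / n,
        "frac_both": float((s1 & s2).sum()) / n,
        "n_degs": int(n),
    }


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
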