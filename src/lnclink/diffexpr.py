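"""Differential-expression calling: pooled-variance t-test plus fold-change gate.

A probe is called differentially expressed between two sample groups when
both filters pass with strict inequalities: two-sided p from the unpaired
(pooled-variance) Student's t-test below the p cutoff, and linear fold
change — 2^|mean_b - mean_a| of the log2 group means — above the FC cutoff.
Boundary values (p equal to the cutoff, FC exactly 1.5) fail.  Raw p-values
gate the calls; a Benjamini-Hochberg FDR column is emitted for reference
but never used for gating by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Contrast, ExpressionMatrix, LOG2, ProbeAnnotation, SampleTable, ValidationError

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def _pooled_t_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t over rows of a and b.

    Returns (t, p, degenerate).  Zero pooled variance with equal means gives
    t=0, p=1; zero pooled variance with unequal means is flagged degenerate
    and reported as p=0 with t = +/-inf.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("each group needs at least 2 samples for the t-test")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled_var = ss / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    delta = mean_b - mean_a
    degenerate = (se == 0) & (delta != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t[degenerate] = np.sign(delta[degenerate]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df)
    p = np.where(se == 0, np.where(degenerate, 0.0, 1.0), p)
    return t, p, degenerate


def student_t_test(a, b) -> TTestResult:
    """Unpaired pooled-variance Student's t-test, two-sided.

    Pooled variance with df = n_a + n_b - 2; each group must contribute at
    least two finite values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("t-test inputs must be finite")
    t, p, degen = _pooled_t_arrays(a[None, :], b[None, :])
    return TTestResult(float(t[0]), float(p[0]), bool(degen[0]))


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Linear fold change 2^|mean_b - mean_a| and direction of change.

    Means are log2 values; direction is "up" when mean_b > mean_a.  A zero
    delta reports FC 1 with direction "up" by convention.
    """
    if not (np.isfinite(mean_a) and np.isfinite(mean_b)):
        raise ValidationError("fold change requires finite means")
    delta = mean_b - mean_a
    return float(2.0 ** abs(delta)), (UP if delta >= 0 else DOWN)


def differential_expression(
    m: ExpressionMatrix, samples: SampleTable, contrast: Contrast
) -> pd.DataFrame:
    """Per-probe DE table for one contrast.

    Columns: mean_a, mean_b, delta (log2), fold_change (linear, >=1),
    direction, t_statistic, p_value, degenerate, p_bh, passes_p, passes_fc,
    is_de.  Flags use strict inequalities: p < p_cutoff, FC > fc_cutoff.
    """
    if m.scale != LOG2:
        raise ValidationError("differential expression expects a normalized log2 matrix")
    ids_a, ids_b = contrast.resolve(samples)
    a = m.data[ids_a].to_numpy()
    b = m.data[ids_b].to_numpy()
    t, p, degen = _pooled_t_arrays(a, b)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    delta = mean_b - mean_a
    fc = 2.0 ** np.abs(delta)
    direction = np.where(delta >= 0, UP, DOWN)
    p_bh = multipletests(p, method="fdr_bh")[1]
    passes_p = p < contrast.p_cutoff
    passes_fc = fc > contrast.fc_cutoff
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta": delta,
            "fold_change": fc,
            "direction": direction,
            "t_statistic": t,
            "p_value": p,
            "degenerate": degen,
            "p_bh": p_bh,
            "passes_p": passes_p,
            "passes_fc": passes_fc,
            "is_de": passes_p & passes_fc,
        },
        index=pd.Index(m.probe_ids, name="probe_id"),
    )


def count_by_class(de: pd.DataFrame, ann: ProbeAnnotation) -> pd.DataFrame:
    """Counts of DE probes by probe class and direction (the up/down summary).

    Returns a class x direction table whose entries sum to the number of
    is_de rows.  Every probe in the table must be annotated.
    """
    classes = ann.classes_for(de.index)
    sub = de.loc[de["is_de"]]
    table = pd.DataFrame(
        0,
        index=pd.Index(["lncRNA", "mRNA"], name="probe_class"),
        columns=pd.Index([UP, DOWN], name="direction"),
    )
    if len(sub):
        counts = (
            pd.DataFrame({"probe_class": classes.loc[sub.index].to_numpy(), "direction": sub["direction"]})
            .value_counts()
            .unstack(fill_value=0)
        )
        table = table.add(counts, fill_value=0).astype(int)[[UP, DOWN]].loc[["lncRNA", "mRNA"]]
    return table


def de_union(de_tables: dict[str, pd.DataFrame]) -> set:
    """Union of is_de probe ids over contrasts.

    This is how the radiation-responsive set is formed: per strain, the
    union over that strain's timepoint contrasts; across strains, the union
    over all contrasts ("differentially expressed in either strain").
    """
    out: set = set()
    for table in de_tables.values():
        out |= set(table.index[table["is_de"]])
    return out
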