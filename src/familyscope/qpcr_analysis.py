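"""qRT-PCR relative expression (2^-ddCt), ANOVA + Duncan letters, networks.

Relative quantification follows Livak: per replicate dCt = Ct(target) -
Ct(reference); ddCt subtracts the mean calibrator dCt (0 h by default);
rq = 2^-ddCt with amplification efficiency fixed at 2.  The summary rq per
condition is 2^-(mean ddCt), i.e. the geometric mean of the replicate rqs,
which makes the calibrator's summary exactly 1 by construction.

Timepoint effects are tested with one-way ANOVA followed by Duncan's
multiple range test at alpha = 0.05: means are ordered, the critical range
for a span of p means is q(alpha_p, p, df_error) * sqrt(MSE/n) with
Duncan's protection level alpha_p = 1 - (1 - alpha)^(p-1), and letters are
assigned by the standard stepwise procedure.  Letters are only split when
the omnibus F test is itself significant.

Co-regulatory networks keep gene pairs with |Pearson r| above a floor
(default 0.5) and p < 0.05 over the timepoint means, retaining the sign -
published figures display negative-correlation edges, so the magnitude is
thresholded, not the signed value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .expression_analysis import CoexpressionEdge

logger = logging.getLogger("familyscope")

CT_COLUMNS = (
    "gene_id",
    "treatment",
    "timepoint",
    "replicate",
    "ct_target",
    "ct_reference",
)


@dataclass
class RelativeExpression:
    """Per-replicate and summary 2^-ddCt values."""

    replicates: pd.DataFrame  # gene_id, treatment, timepoint, replicate, rq
    summary: pd.DataFrame  # gene_id, treatment, timepoint, mean_rq, sd_rq


def relative_expression(
    ct: pd.DataFrame, calibrator_timepoint: int = 0
) -> RelativeExpression:
    """Livak 2^-ddCt relative expression against a calibrator condition."""
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    ct = ct.copy()
    no_ref = ct["ct_reference"].isna()
    if no_ref.any():
        warnings.warn(f"{int(no_ref.sum())} rows lack a reference Ct; skipped")
        ct = ct[~no_ref]
    rep_rows: list[dict] = []
    sum_rows: list[dict] = []
    for (gene, treatment), block in ct.groupby(["gene_id", "treatment"], sort=True):
        dct = block["ct_target"] - block["ct_reference"]
        cal = dct[block["timepoint"] == calibrator_timepoint]
        if cal.empty:
            raise ValueError(
                f"no calibrator rows (timepoint {calibrator_timepoint}) for "
                f"{gene}/{treatment}"
            )
        ddct = dct - cal.mean()
        rq = np.power(2.0, -ddct)
        for (_, row), rq_val, ddct_val in zip(block.iterrows(), rq, ddct):
            rep_rows.append(
                {
                    "gene_id": gene,
                    "treatment": treatment,
                    "timepoint": row["timepoint"],
                    "replicate": row["replicate"],
                    "ddct": float(ddct_val),
                    "rq": float(rq_val),
                }
            )
        for tp, tp_block in pd.DataFrame(
            {"timepoint": block["timepoint"], "ddct": ddct, "rq": rq}
        ).groupby("timepoint"):
            sum_rows.append(
                {
                    "gene_id": gene,
                    "treatment": treatment,
                    "timepoint": tp,
                    "mean_rq": float(2.0 ** (-tp_block["ddct"].mean())),
                    "sd_rq": float(tp_block["rq"].std(ddof=1)),
                }
            )
    return RelativeExpression(
        replicates=pd.DataFrame(rep_rows), summary=pd.DataFrame(sum_rows)
    )


@dataclass
class DuncanResult:
    table: pd.DataFrame  # group, mean, letters (ordered by descending mean)
    f_stat: float
    anova_p: float
    mse: float
    df_error: int


@lru_cache(maxsize=None)
def _duncan_q(span: int, df_error: int, alpha: float) -> float:
    # protection level alpha_p = 1 - (1-alpha)^(span-1)
    quantile = (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(quantile, span, df_error))


def anova_duncan(groups: dict[str, np.ndarray], alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA with Duncan's multiple range test letters.

    ``groups`` maps group label -> replicate values (equal n per group).
    Groups sharing a letter are not significantly different at ``alpha``.
    The letter split is protected by the omnibus F test: a non-significant
    ANOVA yields a single shared letter.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    sizes = {len(a) for a in arrays}
    if len(sizes) != 1:
        raise ValueError("Duncan's test requires equal group sizes")
    n = sizes.pop()
    if n < 2:
        raise ValueError("need >= 2 replicates per group")
    k = len(labels)
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = n * float(((means - grand) ** 2).sum())
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = k - 1
    df_error = k * (n - 1)
    msb = ss_between / df_between
    mse = ss_within / df_error
    if mse == 0.0:
        if np.allclose(means, means[0]):
            f_stat, anova_p = float("nan"), 1.0
        else:
            f_stat, anova_p = float("inf"), 0.0
    else:
        f_stat = msb / mse
        anova_p = float(stats.f.sf(f_stat, df_between, df_error))

    order = np.argsort(-means, kind="stable")
    sorted_means = means[order]
    sorted_labels = [labels[i] for i in order]

    nonsig: set[tuple[int, int]] = set()
    if anova_p >= alpha:
        nonsig = {(i, j) for i in range(k) for j in range(i + 1, k)}
    else:
        def critical_range(span: int) -> float:
            if mse == 0.0:
                return 0.0
            return _duncan_q(span, df_error, alpha) * np.sqrt(mse / n)

        def test_span(i: int, j: int) -> None:
            if i >= j:
                return
            if sorted_means[i] - sorted_means[j] <= critical_range(j - i + 1):
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        nonsig.add((a, b))
            else:
                test_span(i, j - 1)
                test_span(i + 1, j)

        test_span(0, k - 1)

    # maximal homogeneous intervals -> letters
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            (a, b) in nonsig for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        if not any(lo <= i and j <= hi for lo, hi in intervals):
            intervals.append((i, j))
    letters = [""] * k
    for letter_idx, (lo, hi) in enumerate(intervals):
        letter = chr(ord("a") + letter_idx)
        for pos in range(lo, hi + 1):
            letters[pos] += letter

    table = pd.DataFrame(
        {"group": sorted_labels, "mean": sorted_means, "letters": letters}
    )
    return DuncanResult(table, f_stat, anova_p, mse, df_error)


def qpcr_network(
    profiles: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> list[CoexpressionEdge]:
    """Co-regulatory edges over per-gene timepoint profiles.

    ``profiles`` is genes x timepoints (e.g. summary rq means for one
    treatment).  Pairs with |r| > ``r_min`` and p < ``p_max`` are kept with
    their sign; constant profiles are excluded with a warning.  Output is
    sorted canonically, so it is invariant to gene input order.
    """
    if profiles.shape[1] < 4:
        raise ValueError("need >= 4 timepoints")
    usable: list[str] = []
    for gene in profiles.index:
        if np.ptp(profiles.loc[gene].to_numpy(float)) == 0:
            warnings.warn(f"constant profile; excluding gene {gene}")
        else:
            usable.append(gene)
    edges: list[CoexpressionEdge] = []
    n = profiles.shape[1]
    for idx, gene_a in enumerate(sorted(usable)):
        for gene_b in sorted(usable)[idx + 1 :]:
            r, p = stats.pearsonr(
                profiles.loc[gene_a].to_numpy(float),
                profiles.loc[gene_b].to_numpy(float),
            )
            if abs(r) > r_min and p < p_max:
                edges.append(CoexpressionEdge(gene_a, gene_b, float(r), float(p), n))
    return edges
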