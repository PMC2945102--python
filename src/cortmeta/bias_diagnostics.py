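"""Small-study-effects diagnostics: Harbord's score test and
contour-enhanced funnel plots.

Harbord's modified test replaces the observed log-OR of Egger-type
regressions with the efficient score of the conditional likelihood under
the null: for a 2x2 table with ``a`` treated events, arm sizes ``n1, n0``,
``m`` total events and ``N = n1 + n0``,

    Z = a - m n1 / N,      V = m (N - m) n1 n0 / (N^2 (N - 1)).

The test is an ordinary least-squares regression of ``Z / sqrt(V)`` on
``sqrt(V)``; a non-zero intercept signals an association between effect and
precision (a small-study effect), assessed by a two-sided t-test on
``n - 2`` degrees of freedom.  The score form behaves well when events are
sparse and heterogeneity appreciable, where Egger's test is anticonservative.

Contour-enhanced funnel plots display the continuity-corrected observed
log-OR against its standard error, with shaded significance bands
(two-sided p < 0.1, 0.05, 0.01) that depend only on the null, never on the
pooled estimate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .trial_data import ArmCount, DataError, MetaDataset, observed_log_or

__all__ = [
    "ScoreComponents",
    "HarbordResult",
    "score_components",
    "harbord_test",
    "contour_funnel_plot",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreComponents:
    """Efficient score and its variance for one trial under the null."""

    z: float
    v: float


@dataclass(frozen=True)
class HarbordResult:
    intercept: float
    intercept_se: float
    t_stat: float
    p_value: float
    df: int
    n_trials: int

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "se": self.intercept_se,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "n_trials": self.n_trials,
        }


def score_components(steroid: ArmCount, control: ArmCount) -> ScoreComponents:
    """Score ``Z`` (observed minus expected treated events) and variance ``V``.

    Degenerate tables (no events, or all events, across both arms) carry no
    information about the odds ratio and raise :class:`DataError`.
    """
    a = steroid.events
    n1 = steroid.total
    n0 = control.total
    m = steroid.events + control.events
    N = n1 + n0
    if m == 0 or m == N:
        raise DataError(
            "degenerate 2x2 table (all events or no events); no score information"
        )
    z = a - m * n1 / N
    v = m * (N - m) * n1 * n0 / (N**2 * (N - 1))
    return ScoreComponents(z=float(z), v=float(v))


def harbord_test(data: MetaDataset) -> HarbordResult:
    """Harbord's modified score test for small-study effects.

    Degenerate trials are dropped with a logged notice; at least three
    informative trials are required.
    """
    zs, vs = [], []
    for t in data.trials:
        try:
            sc = score_components(t.steroid, t.control)
        except DataError:
            logger.info("harbord_test drops degenerate trial %s", t.trial_id)
            continue
        zs.append(sc.z)
        vs.append(sc.v)
    n = len(zs)
    if n < 3:
        raise DataError(f"Harbord test needs >= 3 informative trials, got {n}")
    z = np.asarray(zs)
    v = np.asarray(vs)
    y = z / np.sqrt(v)
    x = np.sqrt(v)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return HarbordResult(
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        t_stat=float(fit.tvalues[0]),
        p_value=float(fit.pvalues[0]),
        df=int(fit.df_resid),
        n_trials=n,
    )


def write_harbord_json(result: HarbordResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.as_dict(), fh, indent=2)


#: contour levels: two-sided p thresholds and grey shades, outermost first
_CONTOURS = ((0.01, "0.55"), (0.05, "0.7"), (0.1, "0.85"))


def contour_funnel_plot(data: MetaDataset, out_path, correction: float = 0.5):
    """Write a contour-enhanced funnel plot (log-OR vs SE, SE axis inverted).

    Shaded bands mark where ``|log OR| / SE`` exceeds the two-sided normal
    critical value for p < 0.1, 0.05 and 0.01; they depend only on the null
    hypothesis, so a biased pooled estimate cannot move them.  The output
    format follows the file extension (png, svg, pdf...).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = np.array(
        [observed_log_or(t.steroid, t.control, correction) for t in data.trials]
    )
    lors, ses = points[:, 0], points[:, 1]
    se_max = float(ses.max()) * 1.15
    span = max(float(np.abs(lors).max()), norm.isf(0.005) * se_max) * 1.1
    se_grid = np.linspace(1e-9, se_max, 200)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.fill_betweenx(
        se_grid, -span, span, color=_CONTOURS[0][1], zorder=0, label="p < 0.01"
    )
    for (p_outer, _), (p_inner, shade) in zip(_CONTOURS, _CONTOURS[1:] + ((None, "1.0"),)):
        crit = norm.isf(p_outer / 2) * se_grid
        label = f"p < {p_inner}" if p_inner is not None else "p > 0.1"
        ax.fill_betweenx(se_grid, -crit, crit, color=shade, zorder=0, label=label)
    ax.scatter(lors, ses, zorder=3, facecolor="black", s=25)
    ax.set_ylim(se_max, 0)
    ax.set_xlim(-span, span)
    ticks = [0.1, 0.25, 0.5, 1, 2, 4, 8]
    ticks = [t for t in ticks if abs(np.log(t)) <= span]
    ax.set_xticks(np.log(ticks))
    ax.set_xticklabels([str(t) for t in ticks])
    ax.set_xlabel("odds ratio (log scale)")
    ax.set_ylabel("standard error")
    ax.set_title(f"{data.outcome}, {data.stratum_label} (n = {len(data)})")
    ax.legend(loc="upper right", fontsize=8, frameon=True)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
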