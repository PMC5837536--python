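"""Forest-style bias-component and negative-control plots.

Conventions follow the usual covariate-balance figure style: one row per
covariate/outcome, filled square marker for the conventional (OLS) estimate,
open circle for the IV estimate, horizontal whiskers for robust confidence
intervals, and a vertical reference line at zero.  SVG is the primary output
format (deterministic text, byte-identical for fixed input); PNG is also
supported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import
import matplotlib.pyplot as plt

from .balance_tests import BalanceReport
from .negative_controls import NCOutcomeResult, NCReport

# fixed hash salt + scrubbed metadata make SVG output reproducible byte-for-byte
_SVG_RC = {"svg.hashsalt": "ivbalance", "svg.fonttype": "none"}


def _save(fig, path: Path) -> None:
    kwargs = {}
    if path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    with matplotlib.rc_context(_SVG_RC):
        fig.savefig(path, **kwargs)
    plt.close(fig)


def _forest(rows, title: str, path: Path, show_ci: bool, scale_label: str) -> None:
    """rows: list of (label, (est, lo, hi) or None, (est, lo, hi) or None)."""
    if not rows:
        raise ValueError("nothing to plot: no non-degenerate rows")
    n = len(rows)
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.4 * n + 1.2)))
    ypos = list(range(n, 0, -1))
    for y, (label, filled, open_) in zip(ypos, rows):
        if filled is not None:
            est, lo, hi = filled
            if show_ci:
                ax.plot([lo, hi], [y + 0.12, y + 0.12], color="black", lw=1.2,
                        zorder=2, gid="whisker")
            ax.plot([est], [y + 0.12], marker="s", color="black", ms=5,
                    ls="none", zorder=3, gid="marker")
        if open_ is not None:
            est, lo, hi = open_
            if show_ci:
                ax.plot([lo, hi], [y - 0.12, y - 0.12], color="grey", lw=1.2,
                        zorder=2, gid="whisker")
            ax.plot([est], [y - 0.12], marker="o", markerfacecolor="white",
                    color="grey", ms=5, ls="none", zorder=3, gid="marker")
    ax.axvline(0.0, color="0.4", lw=0.8, ls="--", zorder=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels([r[0] for r in rows])
    ax.set_ylim(0.3, n + 0.7)
    ax.set_xlabel(scale_label)
    ax.set_title(title)
    fig.tight_layout()
    _save(fig, path)


def bias_plot(report: BalanceReport, path: Union[str, Path], show_ci: bool = True,
              title: str = "Bias components: conventional (filled) vs IV (open)") -> Path:
    """Render a balance report as a forest plot; returns the output path.

    One row per covariate, in report order.  Degenerate rows are drawn
    without markers; an all-degenerate report is an error.
    """
    path = Path(path)
    rows = []
    any_live = False
    for p in report.pairs:
        if p.degenerate:
            rows.append((p.covariate, None, None))
            continue
        any_live = True
        rows.append((p.covariate,
                     (p.ols.estimate, p.ols.ci_low, p.ols.ci_high),
                     (p.iv.estimate, p.iv.ci_low, p.iv.ci_high)))
    if not any_live:
        raise ValueError("all rows degenerate; nothing to plot")
    _forest(rows, "Bias components: conventional (filled) vs IV (open)" if title is None else title,
            path, show_ci, "bias component (covariate units)")
    return path


def nc_plot(result: Union[NCOutcomeResult, NCReport], path: Union[str, Path]) -> Path:
    """Render a negative-control result (single outcome or population report)."""
    path = Path(path)
    if isinstance(result, NCOutcomeResult):
        rows = [(result.outcome,
                 (result.conventional.estimate, result.conventional.ci_low,
                  result.conventional.ci_high),
                 None if result.iv is None else
                 (result.iv.estimate, result.iv.ci_low, result.iv.ci_high))]
        title = "Negative-control outcome: conventional (filled) vs IV (open)"
    else:
        rows = []
        for name, est, is_binary in result.rows:
            e = est.scaled(100.0) if is_binary else est
            rows.append((name, (e.estimate, e.ci_low, e.ci_high), None))
        title = "Negative-control population: instrument-outcome associations"
    _forest(rows, title, path, show_ci=True, scale_label="risk/mean difference")
    return path
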