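"""Per-second effect-size dynamics: η² time courses around a light change.

At each relative second the single-second activity is fitted with the same
sequential multi-factor ANOVA used by the MANOVA module, and each term's
effect size η² = SS_term / SS_total is recorded.  Because the sums of
squares are sequential, the per-second η² values of all terms plus the
residual share partition the variance exactly, so the stacked time course
reads as variance shares.  Light-On and Light-Off events are never mixed in
one fit.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .activity import METADATA_COLUMNS, WindowedActivitySet
from .errors import ValidationError
from .manova import DesignSpec, build_design, sequential_anova

logger = logging.getLogger(__name__)


def anova_eta_squared(y: np.ndarray, design: DesignSpec) -> pd.DataFrame:
    """Sequential per-term SS, df and η² for a single response vector.

    η² = SS_term / SS_total with SS_total the centered total sum of squares.
    A constant response has zero total SS; every η² is then defined as 0
    (with a logged warning) rather than 0/0.
    """
    tab = sequential_anova(y, design)
    ss_total = float(tab["ss"].sum())
    # a constant response leaves only rounding noise in the centered SS
    if ss_total <= 1e-12 * max(1.0, float(np.sum(np.square(y)))):
        logger.warning("constant response: total SS is 0, all eta^2 set to 0")
        tab["eta_squared"] = 0.0
    else:
        tab["eta_squared"] = tab["ss"] / ss_total
    tab["ss_total"] = ss_total
    return tab


def dynamic_effect_timecourse(
    windows: WindowedActivitySet,
    terms,
    stimulus: str,
    filters: dict | None = None,
) -> pd.DataFrame:
    """η² of every model term at each relative second for one stimulus type.

    Fits :func:`anova_eta_squared` on the activity at each relative second
    (−pre_len+1 .. post_len) using the given ordered term list, restricted
    to Light-On or Light-Off events.  Returns a long-form table with columns
    ``stimulus, rel_second, term, ss, df, eta_squared, n``.
    """
    stimulus = stimulus.lower()
    if stimulus not in ("on", "off"):
        raise ValidationError(f"stimulus must be 'on' or 'off', got {stimulus!r}")
    df = windows.data[windows.data["stimulus"] == stimulus]
    for col, val in (filters or {}).items():
        vals = val if isinstance(val, (list, tuple, set)) else [val]
        df = df[df[col].isin(list(vals))]
    if df.empty:
        raise ValidationError(f"no windows with stimulus {stimulus!r}")
    # one metadata row per (animal, event) observation, in a fixed order
    obs = (
        df.drop_duplicates(["animal_id", "event_time_s"])
        .set_index(["animal_id", "event_time_s"])
        .sort_index()[METADATA_COLUMNS + ["trial_index"]]
    )
    design = build_design(obs.reset_index(), terms)
    wide = (
        df.pivot_table(
            index=["animal_id", "event_time_s"],
            columns="rel_second",
            values="activity",
            aggfunc="first",
        )
        .sort_index()
        .sort_index(axis=1)
    )
    if wide.isna().any().any():
        raise ValidationError("windows contain missing seconds")
    out = []
    for rel_second in wide.columns:
        tab = anova_eta_squared(wide[rel_second].to_numpy(), design)
        tab.insert(0, "rel_second", int(rel_second))
        tab.insert(0, "stimulus", stimulus)
        tab["n"] = len(wide)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def plot_timecourse(timecourse: pd.DataFrame, path) -> None:
    """Stacked per-term η² traces over relative seconds, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    terms = [t for t in timecourse["term"].unique() if t != "residual"]
    for term in terms:
        sub = timecourse[timecourse["term"] == term]
        ax.plot(sub["rel_second"], 100 * sub["eta_squared"], label=term)
    ax.axvline(0.5, color="k", lw=0.8, ls="--")
    ax.set_xlabel("seconds relative to light change")
    ax.set_ylabel(r"effect size $\eta^2$ (%)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
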