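"""Optional figures: trajectory spaghetti plots and prediction curves."""

from __future__ import annotations

from .datatypes import AnalysisDataset, DynamicPrediction


def plot_trajectories(data: AnalysisDataset, ax=None, log_scale: bool = True):
    """Spaghetti plot of per-subject trajectories split by prospective event
    status, with a LOWESS moving average per group."""
    import matplotlib.pyplot as plt
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    ev = data.patients.set_index("patient_id")["event_type"]
    vis = data.visits.copy()
    vis["vte"] = vis["patient_id"].map(ev) == "vte"
    ycol = "log2_ddimer" if log_scale else "ddimer_ugml"
    for k, (flag, label, style) in enumerate(
        [(False, "no VTE", "-"), (True, "VTE", "--")]
    ):
        sub = vis[vis["vte"] == flag]
        for _, g in sub.groupby("patient_id"):
            ax[k].plot(g["time"], g[ycol], style, color="0.7", lw=0.6)
        if len(sub) > 5:
            sm = lowess(sub[ycol], sub["time"], frac=0.6)
            ax[k].plot(sm[:, 0], sm[:, 1], style, color="k", lw=2)
        ax[k].set_title(label)
        ax[k].set_xlabel(f"time ({data.time_unit})")
    ax[0].set_ylabel("log2 D-dimer" if log_scale else "D-dimer (ug/mL)")
    return ax


def plot_prediction(pred: DynamicPrediction, history=None, ax=None):
    """Conditional risk curve with its 95% band; optionally the biomarker
    history on a twin axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pred.horizons, pred.risk, "k-", label="conditional VTE risk")
    ax.fill_between(pred.horizons, pred.ci_lower, pred.ci_upper, alpha=0.25, color="C3")
    ax.axvline(pred.landmark, ls="-.", color="C3")
    ax.set_xlabel(f"time ({pred.time_unit})")
    ax.set_ylabel("P(VTE by u | event-free at s, history)")
    ax.set_ylim(0, 1)
    if history is not None:
        ax2 = ax.twinx()
        ax2.plot(history["time"], history["ddimer_ugml"], "o-", color="C0", ms=4)
        ax2.set_ylabel("D-dimer (ug/mL)", color="C0")
    ax.legend(loc="upper left")
    return ax
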