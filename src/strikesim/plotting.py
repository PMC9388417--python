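"""Basic plots for batch results: learning curves and belief densities."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import ExperimentResult, beta_summary


def plot_learning_curve(result: ExperimentResult, ax=None, window: int = 5):
    """Mean anticipate-normal proportion and success across trials.

    Curves are smoothed with a short moving mean for display only; summary
    statistics elsewhere always use the raw per-trial means.
    """
    ax = ax or plt.gca()
    pt = result.per_trial
    smooth = pt["mean_normal_prop"].rolling(window, min_periods=1).mean()
    ax.fill_between(pt["trial"], pt["ci_low"], pt["ci_high"],
                    alpha=0.3, color="lightblue", label="95% CI")
    ax.plot(pt["trial"], smooth, color="goldenrod", label="anticipate normal")
    ax.plot(pt["trial"], pt["mean_success"].rolling(window, min_periods=1).mean(),
            color="seagreen", label="success")
    ax.set_xlabel("trial")
    ax.set_ylabel("proportion")
    ax.set_ylim(0, 1)
    ax.set_title(result.condition.name)
    ax.legend(frameon=False)
    return ax


def plot_belief_density(result: ExperimentResult, ax=None):
    """Across-observer Beta density of the learned change-up belief."""
    ax = ax or plt.gca()
    summary = beta_summary(np.array([[result.beta_alpha, result.beta_beta]]))
    ax.plot(summary["grid"], summary["density"], color="slateblue")
    ax.set_xlabel("p(change-up)")
    ax.set_ylabel("density")
    ax.set_title(
        f"{result.condition.name}: Beta({summary['alpha']:.1f}, {summary['beta']:.1f})"
    )
    return ax
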