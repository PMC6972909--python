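"""Optional matplotlib rendering of attribution outputs."""

from __future__ import annotations

import numpy as np

from .attribution import BinnedProfile, ZoneSummary


def plot_binned_profile(profile: BinnedProfile, ax=None):
    """Binned means with +/- SD/2 error bars along the covariate."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ok = profile.included
    ax.errorbar(profile.bin_centers[ok], profile.mean[ok],
                yerr=profile.errorbar_halfwidth[ok], fmt="o-", capsize=3)
    ax.set_xlabel(profile.covariate)
    ax.set_ylabel("mean r_max")
    return ax


def plot_zone_boxes(summaries: list[ZoneSummary], ax=None):
    """Box plot (5/25/50/75/95 quantiles) of r_max per ecological zone,
    with the critical-|r| reference lines."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    stats = [{"label": s.label, "whislo": s.p5, "q1": s.p25, "med": s.p50,
              "q3": s.p75, "whishi": s.p95, "fliers": []} for s in summaries]
    ax.bxp(stats, showfliers=False)
    if summaries:
        ax.axhline(summaries[0].r_crit_05, color="r", ls="--", lw=0.8)
        ax.axhline(summaries[0].r_crit_001, color="r", ls=":", lw=0.8)
    ax.set_ylabel("r_max")
    ax.tick_params(axis="x", rotation=60)
    return ax


def plot_zone_temporal_profiles(medians, ax=None):
    """Per-zone median r_j against cumulation period, one line per lag."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    arr = np.asarray(medians)
    for row, zone in zip(arr, getattr(medians, "index", range(len(arr)))):
        prof = row.reshape(4, 6)
        for lag in range(4):
            ax.plot(np.arange(1, 7), prof[lag], marker="o", ms=2, lw=0.8,
                    label=f"zone {zone} lag {lag}")
    ax.set_xlabel("cumulation period (months)")
    ax.set_ylabel("median r_j")
    return ax
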