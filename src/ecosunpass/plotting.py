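"""Dot-and-range chart of per-substance hazard scores (real dot, best-worst whiskers)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .hazard_scoring import OVERALL_MAX, OVERALL_MIN, HazardTriple

__all__ = ["plot_hazard_ranges"]


def plot_hazard_ranges(triples: dict[str, HazardTriple], path=None, ax=None):
    """Real-case score as a dot with a best-to-worst uncertainty whisker per
    substance; a wide whisker flags a data-poor dossier."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.4 * len(triples)), 4))
    keys = list(triples)
    x = range(len(keys))
    real = [triples[k].real.overall for k in keys]
    lo = [triples[k].real.overall - triples[k].best.overall for k in keys]
    hi = [triples[k].worst.overall - triples[k].real.overall for k in keys]
    ax.errorbar(x, real, yerr=[lo, hi], fmt="o", color="black", capsize=3, lw=1)
    ax.set_xticks(list(x))
    ax.set_xticklabels(keys, rotation=90)
    ax.set_ylabel("environmental hazard score")
    ax.set_ylim(OVERALL_MIN - 0.25, OVERALL_MAX + 0.25)
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
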