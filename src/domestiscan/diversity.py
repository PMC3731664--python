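"""Nucleotide diversity, Watterson's theta, and the wild/cultivated contrast.

Pi is the Nei–Li average pairwise difference per site with *pairwise*
deletion: each pair of sequences is compared only at columns where both
carry a concrete base (no gap, no N), and the effective length is the mean
number of compared sites across pairs — equivalently, pi = total pairwise
differences / total pairwise compared sites.  A selective sweep (here,
domestication) leaves pi near zero in the selected population while the
wild progenitor retains diversity; the per-window ratio
pi_cultivated / pi_wild is the scan statistic.

Watterson's theta uses complete deletion: S segregating sites among
columns with a concrete base in every sequence of the subset, scaled by
the harmonic number a1 = sum_{i<n} 1/i and the masked length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomestiscanError
from .panel_io import Panel

__all__ = [
    "nucleotide_diversity",
    "watterson_theta",
    "sliding_diversity",
    "diversity_ratio",
    "diversity_contrast",
    "DiversityWindow",
]


def _as_array(sequences) -> np.ndarray:
    seqs = list(sequences)
    if len(seqs) < 2:
        raise DomestiscanError("need >= 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise DomestiscanError(f"sequences differ in length: {sorted(lengths)}")
    return np.array([list(s) for s in seqs])


def nucleotide_diversity(sequences) -> float:
    """Per-site pi over an aligned set of sequences (pairwise deletion).

    Returns 0.0 when every pair is identical on its compared sites (or no
    sites are comparable at all).
    """
    arr = _as_array(sequences)
    valid = (arr != "-") & (arr != "N")
    n = arr.shape[0]
    total_diff = 0
    total_sites = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            total_sites += int(mask.sum())
            total_diff += int(((arr[i] != arr[j]) & mask).sum())
    if total_sites == 0:
        return 0.0
    return total_diff / total_sites


def watterson_theta(sequences) -> float:
    """Per-site Watterson's theta_w = S / (a1 * L_eff), complete deletion."""
    arr = _as_array(sequences)
    n = arr.shape[0]
    valid = ((arr != "-") & (arr != "N")).all(axis=0)
    l_eff = int(valid.sum())
    if l_eff == 0:
        return 0.0
    sub = arr[:, valid]
    segregating = int((sub != sub[0]).any(axis=0).sum())
    a1 = sum(1.0 / i for i in range(1, n))
    return segregating / (a1 * l_eff)


@dataclass
class DiversityWindow:
    """Per-window diversity for both groups, in upstream-bp coordinates.

    ``start_upstream_bp`` is the inclusive distal bound, ``end_upstream_bp``
    the exclusive proximal bound (positions decrease toward the gene).
    """

    start_upstream_bp: int
    end_upstream_bp: int
    pi_wild: float
    pi_cultivated: float
    theta_w_wild: float
    theta_w_cultivated: float
    n_sites_compared: int


def sliding_diversity(
    panel: Panel, window_bp: int = 500, step_bp: int = 100
) -> list[DiversityWindow]:
    """Sliding-window pi and theta_w for wild and cultivated subsets.

    Windows tile the region distal -> proximal; a final partial window is
    kept when it spans at least half a window.
    """
    if window_bp < 50:
        raise DomestiscanError("window_bp must be >= 50")
    if step_bp < 1:
        raise DomestiscanError("step_bp must be >= 1")
    groups = {}
    for g in ("wild", "cultivated"):
        members = panel.members(g)
        if len(members) < 2:
            raise DomestiscanError(f"group {g!r} has fewer than 2 members")
        groups[g] = [panel.sequences[m] for m in members]
    L = panel.length
    windows: list[DiversityWindow] = []
    start = 0
    while start < L:
        end = min(start + window_bp, L)
        width = end - start
        if width < window_bp and width < window_bp / 2:
            break
        sub = {g: [s[start:end] for s in seqs] for g, seqs in groups.items()}
        all_sub = sub["wild"] + sub["cultivated"]
        arr = np.array([list(s) for s in all_sub])
        compared = int(((arr != "-") & (arr != "N")).all(axis=0).sum())
        windows.append(
            DiversityWindow(
                start_upstream_bp=panel.anchor_upstream_bp - start,
                end_upstream_bp=panel.anchor_upstream_bp - end,
                pi_wild=nucleotide_diversity(sub["wild"]),
                pi_cultivated=nucleotide_diversity(sub["cultivated"]),
                theta_w_wild=watterson_theta(sub["wild"]),
                theta_w_cultivated=watterson_theta(sub["cultivated"]),
                n_sites_compared=compared,
            )
        )
        if end == L:
            break
        start += step_bp
    return windows


def diversity_ratio(pi_wild: float, pi_cultivated: float) -> float:
    """pi_cultivated / pi_wild; nan when 0/0, inf when only pi_wild is 0."""
    if pi_wild < 0 or pi_cultivated < 0:
        raise DomestiscanError("pi must be non-negative")
    if pi_wild == 0:
        return math.nan if pi_cultivated == 0 else math.inf
    return pi_cultivated / pi_wild


def diversity_contrast(
    panel: Panel,
    window_bp: int = 500,
    step_bp: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean per-window diversity ratio with a bootstrap CI over windows.

    The sweep signature is a cultivated/wild pi ratio well below 1.  The
    CI resamples windows with replacement (seeded); no parametric test is
    attached to the contrast.
    """
    windows = sliding_diversity(panel, window_bp, step_bp)
    pw = np.array([w.pi_wild for w in windows])
    pc = np.array([w.pi_cultivated for w in windows])
    mean_ratio = diversity_ratio(float(pw.mean()), float(pc.mean()))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(windows), size=(n_boot, len(windows)))
    boot_w = pw[idx].mean(axis=1)
    boot_c = pc[idx].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_ratio = boot_c / boot_w
    lo, hi = np.nanpercentile(boot_ratio, [2.5, 97.5])
    return {
        "mean_pi_wild": float(pw.mean()),
        "mean_pi_cultivated": float(pc.mean()),
        "ratio": mean_ratio,
        "ratio_ci95": (float(lo), float(hi)),
        "n_windows": len(windows),
    }
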