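"""Bootstrap resampling design and selection-stability metrics.

Feature-selection stability is assessed by refitting on many "bootstrap"
subsamples (sampling *without* replacement — the term is kept for
traceability with common usage in this literature) and comparing the
selected sets pairwise with the Dice coefficient and the chance-corrected
normalized percentage of overlapping genes (nPOG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionRun",
    "StabilityReport",
    "bootstrap_indices",
    "dice",
    "npog",
    "pairwise_stability",
]


@dataclass
class SelectionRun:
    """Selected-feature sets of one resampled fit."""

    run_id: int
    selected: dict[str, set]  # block name -> selected feature labels
    sample_indices: np.ndarray | None = None


@dataclass
class StabilityReport:
    """Mean pairwise stability and per-feature selection frequency."""

    mean_dice: dict[str, float]
    mean_npog: dict[str, float] | None
    selection_frequency: dict[str, dict[str, float]]  # block -> feature -> freq
    n_runs: int = 0


def bootstrap_indices(n: int, fraction: float, n_runs: int,
                      strata=None, seed: int = 0) -> list[np.ndarray]:
    """Index sets of ``n_runs`` subsamples of size floor(fraction * n),
    drawn without replacement.

    With ``strata`` (length-n labels), the draw is stratified: per-stratum
    counts are floor(fraction * n_s) topped up by largest remainder until
    the global count floor(fraction * n) is reached.  Deterministic under
    ``seed``; run r uses child seed ``seed + r``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    total = int(np.floor(fraction * n))
    if strata is None:
        groups = {None: np.arange(n)}
        counts = {None: total}
    else:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata length must equal n")
        groups = {lab: np.flatnonzero(strata == lab) for lab in np.unique(strata)}
        raw = {lab: fraction * len(idx) for lab, idx in groups.items()}
        counts = {lab: int(np.floor(r)) for lab, r in raw.items()}
        # largest remainder to hit the global count
        deficit = total - sum(counts.values())
        order = sorted(groups, key=lambda lab: raw[lab] - counts[lab], reverse=True)
        for lab in order[:deficit]:
            counts[lab] += 1
        for lab, c in counts.items():
            if c < 1:
                raise ValueError(
                    f"stratum {lab!r} retains {c} samples at fraction {fraction}"
                )
            if c > len(groups[lab]):
                raise ValueError(f"stratum {lab!r} smaller than its allocation")
    out = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        idx = np.concatenate([
            rng.choice(groups[lab], size=counts[lab], replace=False)
            for lab in sorted(groups, key=str)
        ])
        out.append(np.sort(idx))
    return out


def dice(a: set, b: set) -> float:
    """Dice similarity 2|a&b| / (|a|+|b|); two empty sets agree perfectly (1)."""
    if not a and not b:
        logger.debug("dice of two empty sets -> 1")
        return 1.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def npog(a: set, b: set, p: int) -> float:
    """Chance-corrected overlap (O - E) / (Omax - E) over a universe of size p.

    O = |a&b|, E = |a||b|/p (expected overlap of uniform random sets of the
    same sizes), Omax = min(|a|,|b|).  Degenerate Omax = E returns 1.
    """
    a, b = set(a), set(b)
    if p < len(a | b):
        raise ValueError(f"universe size {p} smaller than |a|b| = {len(a | b)}")
    O = len(a & b)
    E = len(a) * len(b) / p
    Omax = min(len(a), len(b))
    if abs(Omax - E) < 1e-12:
        return 1.0
    return (O - E) / (Omax - E)


def pairwise_stability(runs: list[SelectionRun], universe_sizes: dict | None = None
                       ) -> StabilityReport:
    """Average the pairwise metrics over all unordered run pairs.

    ``universe_sizes`` maps block name to feature count p (needed for nPOG;
    nPOG is skipped when absent).  Also reports per-feature selection
    frequency across runs.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    block_names = sorted({b for r in runs for b in r.selected})
    mean_dice: dict[str, float] = {}
    mean_npog: dict[str, float] = {}
    freq: dict[str, dict[str, float]] = {}
    n = len(runs)
    for bname in block_names:
        dices, npogs = [], []
        for i in range(n):
            for j in range(i + 1, n):
                a = runs[i].selected.get(bname, set())
                b = runs[j].selected.get(bname, set())
                dices.append(dice(a, b))
                if universe_sizes and bname in universe_sizes:
                    npogs.append(npog(a, b, universe_sizes[bname]))
        mean_dice[bname] = float(np.mean(dices))
        if npogs:
            mean_npog[bname] = float(np.mean(npogs))
        counts: dict[str, int] = {}
        for r in runs:
            for f in r.selected.get(bname, set()):
                counts[f] = counts.get(f, 0) + 1
        freq[bname] = {f: c / n for f, c in counts.items()}
    return StabilityReport(
        mean_dice=mean_dice,
        mean_npog=mean_npog if mean_npog else None,
        selection_frequency=freq,
        n_runs=n,
    )
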