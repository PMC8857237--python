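"""Cumulative ice-nucleation spectra from droplet-freezing dilution assays.

A droplet-freezing assay cools arrays of droplets of a bacterial suspension
along a temperature ramp and records, per temperature, how many droplets have
frozen.  The cumulative concentration of ice-nucleating particles (INPs)
active at or above temperature ``theta``, per colony-forming unit (CFU), is
estimated with the classic dilution-series estimator

    K(theta) = [ln N0 - ln N(theta)] / A

where ``N0`` is the number of droplets tested at one concentration,
``N(theta)`` the number still unfrozen at ``theta``, and ``A`` the mean CFU
per droplet at that concentration.  Because a frozen droplet stays frozen,
frozen counts are cumulative along the ramp and K is non-decreasing as the
temperature falls.

This module estimates K(theta) from replicated multi-dilution assays, makes
presence/absence calls against a water control with an exact one-sided test,
and profiles density-gradient fractions at a fixed test temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .errors import InputError

__all__ = [
    "DropletSeries",
    "FreezingSpectrum",
    "FractionProfile",
    "cumulative_inp_per_cfu",
    "spectrum_from_assay",
    "ina_detectable",
    "fraction_profile",
    "pool_series",
]

#: substitute for N(theta)=0 so the all-frozen point keeps a (lower-bound) value
CENSOR_SUBSTITUTE = 0.5

#: default significance level for the exact one-sided detection test
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DropletSeries:
    """One dilution's droplet counts over the temperature ramp.

    Parameters
    ----------
    strain_id : str
        Strain (or sample) identifier.
    replicate : int
        Replicate number within the assay.
    dilution_factor : float
        Tenfold dilution step relative to the starting concentration
        (1, 10, ... 1e5).
    cfu_per_drop : float
        Mean CFU per droplet at this dilution (symbol ``A``), from dilution
        plating.
    temperatures : tuple of float
        Strictly decreasing Celsius grid, e.g. -2 ... -12.
    n_drops : int
        Droplets tested at this concentration (symbol ``N0``), typically 30.
    frozen_counts : tuple of int
        Cumulative frozen-droplet count at each temperature.
    """

    strain_id: str
    replicate: int
    dilution_factor: float
    cfu_per_drop: float
    temperatures: tuple[float, ...]
    n_drops: int
    frozen_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        object.__setattr__(self, "frozen_counts", tuple(int(f) for f in self.frozen_counts))
        if self.cfu_per_drop <= 0:
            raise InputError(f"cfu_per_drop must be > 0, got {self.cfu_per_drop}")
        if self.dilution_factor <= 0:
            raise InputError(f"dilution_factor must be > 0, got {self.dilution_factor}")
        if self.n_drops < 1:
            raise InputError(f"n_drops must be >= 1, got {self.n_drops}")
        if len(self.temperatures) != len(self.frozen_counts):
            raise InputError("temperatures and frozen_counts differ in length")
        if len(self.temperatures) == 0:
            raise InputError("empty temperature grid")
        if any(b >= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            # grid must strictly decrease (the ramp cools)
            if any(b > a for a, b in zip(self.temperatures, self.temperatures[1:])):
                raise InputError("temperatures must be strictly decreasing")
            raise InputError("temperatures contain duplicates")
        for f in self.frozen_counts:
            if not 0 <= f <= self.n_drops:
                raise InputError(f"frozen count {f} outside [0, {self.n_drops}]")
        if any(b < a for a, b in zip(self.frozen_counts, self.frozen_counts[1:])):
            raise InputError("frozen_counts must be non-decreasing along the ramp")


@dataclass(frozen=True)
class FreezingSpectrum:
    """Cumulative INP-per-CFU curve ``K(theta)`` for one strain.

    ``censored[i]`` is True where every informative dilution had all droplets
    frozen, so ``k_per_cfu[i]`` is only a lower bound.  ``n_series_used[i]``
    counts the pooled dilution series that informed the estimate.
    """

    strain_id: str
    temperatures: tuple[float, ...]
    k_per_cfu: tuple[float, ...]
    censored: tuple[bool, ...]
    n_series_used: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.temperatures)
            == len(self.k_per_cfu)
            == len(self.censored)
            == len(self.n_series_used)
        ):
            raise InputError("spectrum fields differ in length")
        if any(k < 0 for k in self.k_per_cfu):
            raise InputError("k_per_cfu must be non-negative")
        if any(b < a - 1e-12 for a, b in zip(self.k_per_cfu, self.k_per_cfu[1:])):
            raise InputError("k_per_cfu must be non-decreasing along the ramp")


@dataclass(frozen=True)
class FractionProfile:
    """Detection calls for density-gradient fractions at one test temperature."""

    fraction_ids: tuple[int, ...]
    frozen_of_total: tuple[tuple[int, int], ...]
    detectable: tuple[bool, ...]

    @property
    def detectable_ids(self) -> set[int]:
        return {fid for fid, d in zip(self.fraction_ids, self.detectable) if d}


def cumulative_inp_per_cfu(
    n0: int, n_unfrozen: int, a: float
) -> tuple[float, bool]:
    """Estimate cumulative INP per CFU at one temperature.

    Returns ``([ln(n0) - ln(n_unfrozen)] / a, False)`` when at least one
    droplet is unfrozen.  When all droplets froze (``n_unfrozen == 0``) the
    log is undefined; the point is kept as the lower bound obtained by
    substituting 0.5 unfrozen droplets, flagged ``censored=True``.
    """
    if a <= 0:
        raise InputError(f"cfu per drop must be > 0, got {a}")
    if n0 < 1:
        raise InputError(f"droplet count must be >= 1, got {n0}")
    if not 0 <= n_unfrozen <= n0:
        raise InputError(f"unfrozen count {n_unfrozen} outside [0, {n0}]")
    if n_unfrozen == 0:
        return (math.log(n0 / CENSOR_SUBSTITUTE) / a, True)
    return (math.log(n0 / n_unfrozen) / a, False)


def pool_series(series: Sequence[DropletSeries]) -> DropletSeries:
    """Pool replicate series of one dilution by summing droplet counts.

    Droplets are treated as exchangeable across replicates, so pooling sums
    ``n_drops`` and per-temperature frozen counts.  ``cfu_per_drop`` is the
    droplet-number-weighted mean (replicates of one dilution normally share
    it exactly).
    """
    if not series:
        raise InputError("cannot pool an empty list of series")
    grid = series[0].temperatures
    for s in series[1:]:
        if s.temperatures != grid:
            raise InputError("series share no common temperature grid")
    n0 = sum(s.n_drops for s in series)
    frozen = tuple(sum(s.frozen_counts[i] for s in series) for i in range(len(grid)))
    cfus = {s.cfu_per_drop for s in series}
    if len(cfus) == 1:  # the normal case: replicates of one dilution share A exactly
        a = cfus.pop()
    else:
        a = sum(s.cfu_per_drop * s.n_drops for s in series) / n0
    return DropletSeries(
        strain_id=series[0].strain_id,
        replicate=0,
        dilution_factor=series[0].dilution_factor,
        cfu_per_drop=a,
        temperatures=grid,
        n_drops=n0,
        frozen_counts=frozen,
    )


def spectrum_from_assay(
    series: Sequence[DropletSeries],
    combine: Literal["weighted", "most-dilute"] = "weighted",
) -> FreezingSpectrum:
    """Estimate a strain's freezing spectrum from a multi-dilution assay.

    Replicates of each dilution are pooled by count summation, K is computed
    per pooled dilution, and per temperature the informative dilutions
    (``0 < frozen < pooled N0``) are combined:

    ``combine="weighted"``
        droplet-number-weighted mean of K over informative dilutions
        (default).
    ``combine="most-dilute"``
        K of the single most-dilute informative dilution.

    A temperature with no informative dilution is censored (lower bound from
    the most dilute all-frozen series) if any dilution froze completely,
    else K=0.  A final running maximum enforces the cumulative-K
    monotonicity that per-dilution estimates have by construction but a
    changing informative set can transiently break.
    """
    if not series:
        raise InputError("no droplet series supplied")
    if combine not in ("weighted", "most-dilute"):
        raise InputError(f"unknown combine mode {combine!r}")
    grid = series[0].temperatures
    strain = series[0].strain_id
    for s in series:
        if s.temperatures != grid:
            raise InputError(
                f"inconsistent temperature grids across series for {strain}"
            )

    by_dilution: dict[float, list[DropletSeries]] = {}
    for s in series:
        by_dilution.setdefault(s.dilution_factor, []).append(s)
    pooled = [pool_series(group) for _, group in sorted(by_dilution.items())]

    nt = len(grid)
    k_out = np.zeros(nt)
    censored = [False] * nt
    n_used = [0] * nt
    for i in range(nt):
        informative = [p for p in pooled if 0 < p.frozen_counts[i] < p.n_drops]
        if informative:
            ks = np.array(
                [
                    cumulative_inp_per_cfu(
                        p.n_drops, p.n_drops - p.frozen_counts[i], p.cfu_per_drop
                    )[0]
                    for p in informative
                ]
            )
            if combine == "weighted":
                w = np.array([p.n_drops for p in informative], dtype=float)
                k_out[i] = float(np.average(ks, weights=w))
            else:
                most_dilute = max(informative, key=lambda p: p.dilution_factor)
                k_out[i] = cumulative_inp_per_cfu(
                    most_dilute.n_drops,
                    most_dilute.n_drops - most_dilute.frozen_counts[i],
                    most_dilute.cfu_per_drop,
                )[0]
            n_used[i] = len(informative)
        else:
            all_frozen = [p for p in pooled if p.frozen_counts[i] == p.n_drops]
            if all_frozen:
                # tightest lower bound comes from the most dilute saturated series
                best = max(all_frozen, key=lambda p: p.dilution_factor)
                k_out[i] = cumulative_inp_per_cfu(best.n_drops, 0, best.cfu_per_drop)[0]
                censored[i] = True
            # else: nothing frozen anywhere -> K = 0, uncensored

    k_out = np.maximum.accumulate(k_out)
    return FreezingSpectrum(
        strain_id=strain,
        temperatures=grid,
        k_per_cfu=tuple(float(k) for k in k_out),
        censored=tuple(censored),
        n_series_used=tuple(n_used),
    )


def _frozen_exceeds(
    sample_frozen: int, sample_total: int, control_frozen: int, control_total: int,
    alpha: float,
) -> bool:
    """One-sided exact test that the sample's frozen fraction exceeds the control's."""
    table = [
        [sample_frozen, sample_total - sample_frozen],
        [control_frozen, control_total - control_frozen],
    ]
    _, p = fisher_exact(table, alternative="greater")
    return bool(p < alpha)


def ina_detectable(
    sample: DropletSeries | Sequence[DropletSeries],
    control: DropletSeries | Sequence[DropletSeries],
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Call ice-nucleation activity in a sample against a water control.

    True iff at some temperature the sample's frozen fraction significantly
    exceeds the control's under a one-sided exact (Fisher) test at level
    ``alpha``.  Lists of series are pooled first.
    """
    s = pool_series([sample] if isinstance(sample, DropletSeries) else list(sample))
    c = pool_series([control] if isinstance(control, DropletSeries) else list(control))
    if s.temperatures != c.temperatures:
        raise InputError("sample and control share no common temperature grid")
    return any(
        _frozen_exceeds(s.frozen_counts[i], s.n_drops, c.frozen_counts[i], c.n_drops, alpha)
        for i in range(len(s.temperatures))
    )


def fraction_profile(
    counts: Mapping[int, tuple[int, int]],
    blank: tuple[int, int],
    alpha: float = DEFAULT_ALPHA,
) -> FractionProfile:
    """Profile gradient fractions for detectable INA at one fixed temperature.

    ``counts`` maps fraction id (1..12) to ``(frozen, total)`` droplet counts;
    ``blank`` is the water/buffer control's ``(frozen, total)``.  A fraction
    is detectable under the same exact one-sided test used for strain calls.
    """
    if not 1 <= len(counts) <= 12:
        raise InputError(f"expected 1-12 fractions, got {len(counts)}")
    bf, bt = blank
    if bt < 1 or not 0 <= bf <= bt:
        raise InputError(f"invalid blank counts {blank}")
    ids, pairs, flags = [], [], []
    for fid in sorted(counts):
        frozen, total = counts[fid]
        if total < 1 or not 0 <= frozen <= total:
            raise InputError(f"invalid counts {counts[fid]} for fraction {fid}")
        ids.append(int(fid))
        pairs.append((int(frozen), int(total)))
        flags.append(_frozen_exceeds(frozen, total, bf, bt, alpha))
    return FractionProfile(tuple(ids), tuple(pairs), tuple(flags))
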