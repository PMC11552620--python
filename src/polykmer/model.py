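"""Iterative peak decomposition of a polyploid k-mer spectrum.

The k-mer spectrum of a polyploid genome of ploidy ``p`` shows up to ``p``
coverage peaks: k-mers present on exactly ``i`` of the ``p`` homologous
chromosomes accumulate ``i`` times the per-haplotype read depth, so their
coverages concentrate near ``i * C_het``, where ``C_het`` is the observed
k-mer coverage per haplotype chromosome.  The estimator

1. locates the low-coverage cutoff separating sequencing-error k-mers from
   genomic signal (the error spike hugging the y axis),
2. initialises ``C_het`` from the first heterozygous peak,
3. for ``i = 1..p`` fits a normal component centred near ``i * C_het`` to the
   running residual spectrum (scale -> interpolate gaps -> least-squares
   Gaussian fit -> unscale -> subtract),
4. converts each fitted component into a region size
   ``g_i = sum(c * fitted(c)) / (p * C_het)`` and the leftover high-coverage
   mass into a repeat size ``g_{p+1}``,
5. reports the average haploid genome size ``G = sum(g_i, i = 1..p+1)`` and
   the full genome size ``G * p``.

Because every k-mer instance at coverage ``c`` contributes ``c / (p * C_het)``
bases, a region of ``L`` distinct k-mers shared by ``i`` homologs contributes
``L * i / p`` — summing over classes yields the haploid average.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .histogram import KmerHistogram, total_kmer_instances

__all__ = [
    "FitConfig",
    "FitComponent",
    "SizeReport",
    "EstimationError",
    "detect_error_cutoff",
    "estimate_initial_chet",
    "scale_counts",
    "fill_missing",
    "fit_component",
    "subtract_component",
    "region_size",
    "repeat_size",
    "estimate_genome_size",
]

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """Raised when the spectrum does not support a size estimate."""


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the estimator.

    window_half_width_factor
        Each component ``i`` is fitted inside
        ``[i*C_het - f*C_het, i*C_het + f*C_het]``.  At the default 0.5 the
        windows of adjacent components touch without overlapping, which
        prevents double-counting of spectrum mass.
    smoothing_window
        Width (odd) of the centred moving average applied before peak/valley
        detection.  1 disables smoothing.
    error_cutoff_override
        Force the error cutoff instead of detecting it.
    min_peak_prominence
        A candidate first peak must reach this fraction of the tallest
        non-error bin, else the spectrum is treated as homozygous-like.
    min_component_mass_fraction
        The i=1 component must carry at least this fraction of the post-cutoff
        k-mer instances for its fitted mean to replace the initial C_het.
    max_fit_iterations / fit_tolerance
        Passed to the bounded least-squares optimizer.
    joint_refine / overshoot_penalty
        After the sequential pass, re-fit all p components jointly (sum of
        Gaussians, same per-component bounds, initialised from the sequential
        fits).  The sequential pass can leave a small component contaminated
        by a large neighbour's flank; the joint fit removes that coupling.
        Residuals where the fitted sum exceeds the observed counts are
        weighted by ``overshoot_penalty`` (>= 1): over-prediction is
        physically meaningless — more k-mers cannot be subtracted than were
        observed — so the fit is steered to keep the summed curve at or below
        the data, which also keeps the flooring losses of the final
        subtraction small.
    exclude_aggregate_bin
        Drop a counter's ceiling bin (all coverages >= a maximum lumped into
        the final bin) from fitting and size sums.
    repeat_min_coverage_policy
        "above_error_cutoff": repeats are all residual mass at or above the
        error cutoff after the p fits (default).  "above_last_window": only
        residual mass beyond the upper edge of the last fitting window.
    """

    window_half_width_factor: float = 0.5
    smoothing_window: int = 5
    error_cutoff_override: int | None = None
    min_peak_prominence: float = 0.05
    min_component_mass_fraction: float = 1e-3
    max_fit_iterations: int = 20000
    fit_tolerance: float = 1e-12
    joint_refine: bool = True
    overshoot_penalty: float = 3.0
    exclude_aggregate_bin: bool = True
    repeat_min_coverage_policy: str = "above_error_cutoff"

    def __post_init__(self) -> None:
        if not 0 < self.window_half_width_factor <= 0.5:
            raise ValueError("window_half_width_factor must be in (0, 0.5]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.min_peak_prominence < 0:
            raise ValueError("min_peak_prominence must be >= 0")
        if self.overshoot_penalty < 1:
            raise ValueError("overshoot_penalty must be >= 1")
        if self.repeat_min_coverage_policy not in ("above_error_cutoff", "above_last_window"):
            raise ValueError("unknown repeat_min_coverage_policy")


@dataclass(frozen=True)
class FitComponent:
    """One fitted normal peak: k-mers shared by exactly ``index`` homologs.

    ``amplitude`` and ``fitted_curve`` are in raw (unscaled) frequency units;
    ``fitted_curve`` is the Gaussian evaluated on the histogram's full
    coverage grid and clipped below at zero.
    """

    index: int
    mean: float
    sd: float
    amplitude: float
    fitted_curve: np.ndarray
    converged: bool
    window: tuple[float, float]

    @property
    def instances(self) -> float:
        """Total k-mer instances sum(c * fitted(c)) attributed to this peak."""
        grid = np.arange(1, self.fitted_curve.size + 1)
        return float(np.sum(grid * self.fitted_curve))


@dataclass(frozen=True)
class SizeReport:
    """The estimator's deliverable.

    Sizes are in bases, treating distinct-k-mer counts as base counts (for a
    region of length L, L - k + 1 ~ L).  ``region_sizes[i-1]`` is the size of
    the genomic regions shared by exactly i homologous chromosomes;
    ``repeat_size`` the high-coverage leftover attributed to repeats;
    ``genome_size`` the average haploid size G = sum of all of them, and
    ``full_size`` = G * p.
    """

    c_het: float
    ploidy: int
    region_sizes: tuple[float, ...]
    repeat_size: float
    genome_size: float
    full_size: float
    components: tuple[FitComponent, ...]
    error_cutoff: int
    residual_instances: float
    observed_instances: float
    floored_loss: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert len(self.region_sizes) == self.ploidy
        assert all(g >= 0 for g in self.region_sizes)
        assert self.repeat_size >= 0


# ---------------------------------------------------------------------------
# spectrum preprocessing


def _smooth(freq: np.ndarray, width: int) -> np.ndarray:
    # centred moving average; edges normalized by the number of real terms so
    # that edge bins are not attenuated (attenuation would fake a rise at c=1)
    if width <= 1 or freq.size < width:
        return freq.astype(np.float64)
    kernel = np.ones(width)
    sums = np.convolve(freq, kernel, mode="same")
    counts = np.convolve(np.ones_like(freq), kernel, mode="same")
    return sums / counts


def detect_error_cutoff(hist: KmerHistogram, config: FitConfig | None = None) -> int:
    """Coverage below which k-mers are treated as sequencing errors.

    Sequencing errors produce a spike of low-coverage k-mers hugging the
    y axis, so a spectrum with an error peak *descends* from its lowest
    coverages into a valley before rising into the first genomic peak.  The
    rule: follow the (smoothed) frequencies down from coverage 1 and return
    the coverage at which they first turn upward (non-strict descent — a flat
    stretch of empty bins still counts as descending).  If the spectrum rises
    immediately there is no error peak and 1 is returned (nothing excluded);
    if it never turns upward within the lower half of the coverage range, no
    genomic peak is discernible and 1 is returned with a warning.
    """
    config = config or FitConfig()
    if len(hist) < 3:
        raise EstimationError("histogram too short for error-cutoff detection")
    dense = hist.dense()
    s = _smooth(dense.frequencies, config.smoothing_window)
    cov = dense.coverages
    rises = np.flatnonzero(np.diff(s) > 0)
    if rises.size == 0:
        _warnings.warn(
            "spectrum is monotone non-increasing; no genomic peak discernible, "
            "no low-coverage exclusion applied",
            stacklevel=2,
        )
        return 1
    first_rise = int(rises[0])
    if first_rise == 0:
        _warnings.warn(
            "spectrum rises from coverage 1; no error peak detected",
            stacklevel=2,
        )
        return 1
    if first_rise > int(np.ceil(dense.max_coverage / 2)):
        _warnings.warn(
            "no error-peak valley within the lower half of the spectrum; "
            "no low-coverage exclusion applied",
            stacklevel=2,
        )
        return 1
    return int(cov[first_rise])


def estimate_initial_chet(
    hist: KmerHistogram,
    C: float,
    error_cutoff: int,
    config: FitConfig | None = None,
) -> float:
    """Initial per-haplotype coverage from the first heterozygous peak.

    The coverage hint ``C`` must satisfy ``2*C_het < C < 3*C_het``, so the
    first peak lies in the open interval (C/3, C/2); its (smoothed) argmax is
    the initial estimate.  Homozygous-like spectra with no peak there fall
    back to the global non-error argmax divided by the integer that places
    the quotient inside the interval, with a warning.
    """
    config = config or FitConfig()
    if C <= 0:
        raise ValueError("coverage hint C must be positive")
    dense = hist.dense()
    s = _smooth(dense.frequencies, config.smoothing_window)
    cov = dense.coverages
    non_error = cov >= max(error_cutoff, 1)
    if not np.any(non_error & (s > 0)):
        raise EstimationError("spectrum has no signal above the error cutoff")
    tallest = float(np.max(s[non_error]))
    lo, hi = C / 3.0, C / 2.0
    in_interval = non_error & (cov > lo) & (cov < hi)
    if not np.any(in_interval):
        raise EstimationError(
            f"no coverage bins in ({lo:.1f}, {hi:.1f}); re-check the coverage hint C={C}"
        )
    peak_height = float(np.max(s[in_interval]))
    if peak_height >= config.min_peak_prominence * tallest:
        idx = np.flatnonzero(in_interval)
        return float(cov[idx[np.argmax(s[idx])]])
    # homozygous-like: single dominant peak at some multiple of C_het
    global_peak = float(cov[np.flatnonzero(non_error)[np.argmax(s[non_error])]])
    mid = 0.5 * (lo + hi)
    best_n, best_dist = 1, np.inf
    for n in range(1, 65):
        q = global_peak / n
        dist = 0.0 if lo < q < hi else abs(q - mid)
        if dist < best_dist:
            best_n, best_dist = n, dist
        if dist == 0.0:
            break
    est = global_peak / best_n
    _warnings.warn(
        f"no peak in ({lo:.1f}, {hi:.1f}) above {config.min_peak_prominence:.0%} "
        f"prominence; homozygous-like spectrum, falling back to "
        f"{global_peak:.0f}/{best_n} = {est:.2f}",
        stacklevel=2,
    )
    return est


# ---------------------------------------------------------------------------
# the scale / fill / fit / subtract cycle


def _window_mask(hist: KmerHistogram, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (hist.coverages >= lo) & (hist.coverages <= hi)


def scale_counts(
    hist: KmerHistogram, window: tuple[float, float]
) -> tuple[KmerHistogram, float]:
    """Max-normalize frequencies inside the window; bins outside untouched.

    Raw spectrum counts span many orders of magnitude across species; the
    optimizer works on a [0, 1] scale and the returned factor inverts the
    transform exactly.
    """
    mask = _window_mask(hist, window)
    if not np.any(mask):
        raise EstimationError(f"window {window} contains no bins")
    factor = float(np.max(hist.frequencies[mask]))
    if factor <= 0:
        raise EstimationError(f"window {window} has no nonzero frequencies to fit")
    freq = hist.frequencies.copy()
    freq[mask] = freq[mask] / factor
    return hist.with_frequencies(freq), factor


def unscale_counts(
    hist: KmerHistogram, window: tuple[float, float], scale_factor: float
) -> KmerHistogram:
    """Exact inverse of :func:`scale_counts`."""
    mask = _window_mask(hist, window)
    freq = hist.frequencies.copy()
    freq[mask] = freq[mask] * scale_factor
    return hist.with_frequencies(freq)


def fill_missing(hist: KmerHistogram, window: tuple[float, float]) -> KmerHistogram:
    """Give every integer coverage inside the window a bin.

    Absent coverages between present bins get linearly interpolated
    frequencies; absent coverages outside the outermost present bins get 0
    (no extrapolation).
    """
    lo = max(1, int(np.ceil(window[0])))
    hi = int(np.floor(window[1]))
    present = (hist.coverages >= lo) & (hist.coverages <= hi)
    pc = hist.coverages[present]
    pf = hist.frequencies[present]
    if pc.size < 2:
        raise EstimationError(f"window [{lo}, {hi}] has fewer than 2 bins to interpolate")
    want = np.arange(lo, hi + 1, dtype=np.int64)
    interp = np.interp(want, pc, pf)
    interp[(want < pc[0]) | (want > pc[-1])] = 0.0
    # merge window bins back into the full bin list
    outside = (hist.coverages < lo) | (hist.coverages > hi)
    cov = np.concatenate([hist.coverages[outside], want])
    freq = np.concatenate([hist.frequencies[outside], interp])
    order = np.argsort(cov)
    from dataclasses import replace

    return replace(hist, coverages=cov[order], frequencies=freq[order])


def _gaussian(c: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((c - mu) / sigma) ** 2)


def fit_component(
    residual: KmerHistogram,
    i: int,
    C_het: float,
    config: FitConfig | None = None,
) -> FitComponent:
    """Fit one normal peak to the residual spectrum around ``i * C_het``.

    The residual inside ``[i*C_het - w, i*C_het + w]`` (w = half-width factor
    times C_het) is max-normalized and gap-filled, a Gaussian
    ``A * exp(-(c-mu)^2 / (2 sigma^2))`` is fitted by bounded least squares
    (mu confined to the window, sigma in (0, w], A >= 0), and the fitted curve
    is evaluated on the full coverage grid at raw-count scale.  Degenerate
    windows (empty, all-zero) and optimizer failures yield a flat component
    (A = 0, converged = False) rather than an exception.
    """
    config = config or FitConfig()
    if i < 1 or C_het <= 0:
        raise ValueError("need i >= 1 and C_het > 0")
    w = config.window_half_width_factor * C_het
    window = (i * C_het - w, i * C_het + w)
    grid = residual.coverages
    zeros = FitComponent(
        index=i,
        mean=float(i * C_het),
        sd=w / 2.0,
        amplitude=0.0,
        fitted_curve=np.zeros(grid.size),
        converged=False,
        window=window,
    )
    try:
        scaled, factor = scale_counts(residual, window)
        filled = fill_missing(scaled, window)
    except EstimationError as exc:
        logger.warning("component %d: %s; emitting flat component", i, exc)
        return zeros
    mask = _window_mask(filled, window)
    cw = filled.coverages[mask].astype(np.float64)
    fw = filled.frequencies[mask]
    mu0 = float(np.clip(i * C_het, cw[0], cw[-1]))
    a0 = float(fw[np.argmin(np.abs(cw - mu0))]) or 0.5
    p0 = (a0, mu0, w / 2.0)
    bounds = ([0.0, window[0], 1e-6], [np.inf, window[1], w])
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # OptimizeWarning on flat data
            popt, _ = curve_fit(
                _gaussian,
                cw,
                fw,
                p0=p0,
                bounds=bounds,
                maxfev=config.max_fit_iterations,
                ftol=config.fit_tolerance,
                xtol=config.fit_tolerance,
            )
    except (RuntimeError, ValueError) as exc:
        logger.warning("component %d: optimizer failed (%s); flat component", i, exc)
        return zeros
    a_scaled, mu, sigma = (float(v) for v in popt)
    amplitude = a_scaled * factor  # back to raw-count scale
    curve = np.clip(_gaussian(grid.astype(np.float64), amplitude, mu, sigma), 0.0, None)
    return FitComponent(
        index=i,
        mean=mu,
        sd=sigma,
        amplitude=amplitude,
        fitted_curve=curve,
        converged=True,
        window=window,
    )


def subtract_component(
    residual: KmerHistogram, comp: FitComponent
) -> tuple[KmerHistogram, float]:
    """Remove a fitted curve from the residual, flooring at zero.

    Returns the new residual and the flooring loss in k-mer *instances*
    (sum of c times the over-subtracted frequency) — negative frequencies are
    meaningless, but the discarded mass must stay visible so that the
    conservation check (fitted + residual vs observed) remains honest.
    """
    if comp.fitted_curve.size != residual.coverages.size:
        raise EstimationError("component curve and residual are on different grids")
    diff = residual.frequencies - comp.fitted_curve
    loss = float(np.sum(residual.coverages * np.clip(-diff, 0.0, None)))
    if loss > 0:
        logger.info("component %d: floored %.3g k-mer instances", comp.index, loss)
    return residual.with_frequencies(np.clip(diff, 0.0, None)), loss


# ---------------------------------------------------------------------------
# sizes


def region_size(comp: FitComponent, p: int, C_het: float) -> float:
    """Bases shared by exactly ``comp.index`` homologs: sum(c*fitted)/(p*C_het)."""
    if p < 1 or C_het <= 0:
        raise ValueError("need p >= 1 and C_het > 0")
    return comp.instances / (p * C_het)


def repeat_size(
    residual: KmerHistogram,
    p: int,
    C_het: float,
    error_cutoff: int,
    config: FitConfig | None = None,
) -> float:
    """Repeat bases from the residual left after the last component fit.

    The residual mass at coverages at or above the lower bound — the error
    cutoff by default, or the upper edge of the last fitting window under the
    alternate policy — divided by ``p * C_het``.
    """
    config = config or FitConfig()
    if config.repeat_min_coverage_policy == "above_last_window":
        bound = p * C_het + config.window_half_width_factor * C_het
        mask = residual.coverages > bound
        total = float(np.sum(residual.coverages[mask] * residual.frequencies[mask]))
    else:
        total = total_kmer_instances(residual, min_coverage=max(error_cutoff, 1))
    return total / (p * C_het)


def _joint_refine(
    base: KmerHistogram,
    components: list[FitComponent],
    C_het: float,
    cutoff: int,
    config: FitConfig,
) -> list[FitComponent]:
    """Re-fit all components simultaneously as a sum of bounded Gaussians.

    Initialised from the sequential fits; per-component bounds are identical
    to :func:`fit_component`'s.  Overshoot (fitted sum above the observed
    counts) is penalized by ``config.overshoot_penalty``.  Falls back to the
    sequential fits on optimizer failure.
    """
    from scipy.optimize import least_squares

    p = len(components)
    w = config.window_half_width_factor * C_het
    gridf = base.coverages.astype(np.float64)
    mask = (gridf >= cutoff) & (gridf <= p * C_het + w)
    if not np.any(mask) or float(np.max(base.frequencies[mask])) <= 0:
        return components
    scale = float(np.max(base.frequencies[mask]))
    x = gridf[mask]
    y = base.frequencies[mask] / scale
    x0: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    for i, comp in enumerate(components, start=1):
        center = i * C_het
        a = comp.amplitude / scale if comp.converged else 0.0
        mu = comp.mean if comp.converged else center
        sd = comp.sd if comp.converged else w / 2.0
        x0 += [a, float(np.clip(mu, center - w, center + w)), float(np.clip(sd, 1e-6, w))]
        lo += [0.0, center - w, 1e-6]
        hi += [np.inf, center + w, w]
    kappa = config.overshoot_penalty

    def residuals(theta: np.ndarray) -> np.ndarray:
        total = np.zeros_like(x)
        for j in range(p):
            total += _gaussian(x, theta[3 * j], theta[3 * j + 1], theta[3 * j + 2])
        r = total - y
        return np.where(r > 0, kappa * r, r)

    try:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi),
            max_nfev=config.max_fit_iterations,
            ftol=config.fit_tolerance, xtol=config.fit_tolerance,
        )
    except ValueError as exc:
        logger.warning("joint refinement failed (%s); keeping sequential fits", exc)
        return components
    refined = []
    for j, comp in enumerate(components):
        a, mu, sd = (float(v) for v in sol.x[3 * j : 3 * j + 3])
        amplitude = a * scale
        refined.append(
            FitComponent(
                index=comp.index,
                mean=mu,
                sd=sd,
                amplitude=amplitude,
                fitted_curve=np.clip(_gaussian(gridf, amplitude, mu, sd), 0.0, None),
                converged=comp.converged or amplitude > 0,
                window=comp.window,
            )
        )
    return refined


# ---------------------------------------------------------------------------
# orchestration


def estimate_genome_size(
    hist: KmerHistogram,
    p: int,
    C: float,
    config: FitConfig | None = None,
) -> SizeReport:
    """Run the full pipeline and return a :class:`SizeReport`.

    Parameters
    ----------
    hist
        The observed k-mer frequency histogram.
    p
        Ploidy (number of homologous chromosome copies), >= 1.
    C
        Coverage hint satisfying ``2*C_het < C < 3*C_het``; only used to
        bracket the first peak.  For ``p = 1`` the bracket degenerates (the
        only peak *is* C_het) and the global non-error argmax is used instead.
    """
    config = config or FitConfig()
    if p < 1:
        raise ValueError("ploidy must be >= 1")
    caught: list[str] = []

    dense = hist.dense()
    freq = dense.frequencies.copy()
    if hist.aggregate_last_bin and config.exclude_aggregate_bin:
        freq[hist.max_coverage - 1] = 0.0
        caught.append(
            f"excluded counter aggregate bin at coverage {hist.max_coverage}"
        )
        dense = dense.with_frequencies(freq)

    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")
        if config.error_cutoff_override is not None:
            cutoff = int(config.error_cutoff_override)
        else:
            cutoff = detect_error_cutoff(dense, config)

        freq = dense.frequencies.copy()
        freq[: cutoff - 1] = 0.0  # bins with c < cutoff are error k-mers
        residual = dense.with_frequencies(freq)
        observed = total_kmer_instances(residual, min_coverage=cutoff)
        if observed <= 0:
            raise EstimationError("no k-mer instances above the error cutoff")

        if p == 1:
            s = _smooth(residual.frequencies, config.smoothing_window)
            c_het = float(residual.coverages[int(np.argmax(s))])
        else:
            c_het = estimate_initial_chet(residual, C, cutoff, config)

        base = residual
        components: list[FitComponent] = []
        homozygous_like = False
        for i in range(1, p + 1):
            comp = fit_component(residual, i, c_het, config)
            if i == 1:
                if comp.converged and comp.instances >= config.min_component_mass_fraction * observed:
                    c_het = comp.mean  # refine C_het from the first fitted peak
                else:
                    homozygous_like = True
                    caught.append(
                        "first component carries no mass (homozygous-like spectrum); "
                        f"keeping initial C_het = {c_het:.2f}"
                    )
            components.append(comp)
            residual, _ = subtract_component(residual, comp)

        if config.joint_refine:
            components = _joint_refine(base, components, c_het, cutoff, config)
            first = components[0]
            if not homozygous_like and first.instances >= config.min_component_mass_fraction * observed:
                c_het = first.mean

        # final subtraction of the summed curves, floored at zero; the floored
        # mass is logged, not hidden: fitted + residual = observed + floored
        total_curve = np.sum([c.fitted_curve for c in components], axis=0)
        floored = float(
            np.sum(base.coverages * np.clip(total_curve - base.frequencies, 0.0, None))
        )
        residual = base.with_frequencies(
            np.clip(base.frequencies - total_curve, 0.0, None)
        )
        if floored > 0:
            logger.info("flooring losses: %.3g k-mer instances", floored)

        g = [region_size(comp, p, c_het) for comp in components]
        g_rep = repeat_size(residual, p, c_het, cutoff, config)
    caught.extend(str(w.message) for w in wlist)
    for msg in caught:
        logger.warning(msg)

    G = float(sum(g) + g_rep)
    return SizeReport(
        c_het=c_het,
        ploidy=p,
        region_sizes=tuple(g),
        repeat_size=g_rep,
        genome_size=G,
        full_size=G * p,
        components=tuple(components),
        error_cutoff=cutoff,
        residual_instances=total_kmer_instances(residual, min_coverage=cutoff),
        observed_instances=observed,
        floored_loss=floored,
        warnings=tuple(caught),
    )
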