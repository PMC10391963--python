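"""Reconstruct approximate individual patient data from digitized
Kaplan-Meier coordinates and a numbers-at-risk table.

The scheme works interval by interval between consecutive risk-table
times: a candidate number of censorings is placed at uniform quantiles
strictly inside the interval, event counts at each digitized step time are
derived from successive survival-probability ratios
(``S(t)/S(t-) = 1 - d/n``, rounded to the nearest integer, ties to even),
and the censoring count is chosen so that the predicted number at risk at
the next risk-table time matches the published value exactly.  If an
optional total event count is supplied, censoring in the residual tail
(after the last risk-table time) is adjusted so cumulative events match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCurveError, ReconstructionInfeasibleError

__all__ = ["DigitizedCurve", "IPDSet", "KMCurve", "km_curve", "reconstruct_ipd"]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class DigitizedCurve:
    """Monthly KM coordinates + risk table for one endpoint/arm.

    ``times`` start at 0 with survival 1; ``risk_times`` is a subset of the
    reporting grid starting at 0.
    """

    endpoint: str  # "OS" | "PFS"
    arm: str  # "intervention" | "control"
    times: np.ndarray
    surv_probs: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv_probs = np.asarray(self.surv_probs, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)

    def validate(self) -> None:
        t, s = self.times, self.surv_probs
        if t.size == 0 or s.size == 0:
            raise InvalidCurveError(f"{self._tag}: empty curve")
        if t.size != s.size:
            raise InvalidCurveError(f"{self._tag}: times and surv_probs differ in length")
        if t[0] != 0 or abs(s[0] - 1.0) > 1e-12:
            raise InvalidCurveError(f"{self._tag}: curve must start at (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise InvalidCurveError(f"{self._tag}: times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise InvalidCurveError(f"{self._tag}: survival probabilities rise over time")
        if np.any((s < 0) | (s > 1)):
            raise InvalidCurveError(f"{self._tag}: survival probabilities outside [0, 1]")
        if self.risk_times.size == 0 or self.risk_times[0] != 0:
            raise InvalidCurveError(f"{self._tag}: risk table must start at time 0")
        if self.risk_times.size != self.n_at_risk.size:
            raise InvalidCurveError(f"{self._tag}: risk table lengths differ")
        if np.any(np.diff(self.risk_times) <= 0):
            raise InvalidCurveError(f"{self._tag}: risk times must be strictly increasing")
        if np.any(self.n_at_risk < 0):
            raise InvalidCurveError(f"{self._tag}: negative number at risk")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise InvalidCurveError(f"{self._tag}: number at risk must be non-increasing")
        if self.risk_times[-1] > t[-1] + 1e-9:
            raise InvalidCurveError(f"{self._tag}: risk times extend beyond the curve")
        if self.total_events is not None and self.total_events < 0:
            raise InvalidCurveError(f"{self._tag}: negative total event count")

    @property
    def _tag(self) -> str:
        return f"{self.endpoint}/{self.arm}"


@dataclass
class IPDSet:
    """Reconstructed (time, event) records for one endpoint/arm."""

    time: np.ndarray
    event: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


# ---------------------------------------------------------------------------
# product-limit estimator
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier step function, S(0) = 1."""

    event_times: np.ndarray
    surv: np.ndarray  # value of S just after each event time

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        vals = np.concatenate([[1.0], self.surv])
        return vals[idx]

    def __call__(self, t):
        return self.evaluate(t)


def km_curve(ipd: IPDSet) -> KMCurve:
    """Standard product-limit estimator (deaths before censorings at tied
    times, the usual convention)."""
    if ipd.n == 0:
        raise InvalidCurveError("empty IPD set")
    time = ipd.time
    event = ipd.event
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    lo = np.searchsorted(time, uniq, side="left")
    hi = np.searchsorted(time, uniq, side="right")
    n_risk = len(time) - lo
    pe = np.concatenate([[0], np.cumsum(event)])
    d = pe[hi] - pe[lo]
    surv = np.cumprod(1.0 - d / np.maximum(n_risk, 1))
    return KMCurve(event_times=uniq, surv=surv)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def _censor_positions(lo: float, hi: float, c: int, grid: np.ndarray) -> list[float]:
    """c censoring times at uniform quantiles strictly inside (lo, hi),
    nudged off any digitized step time."""
    if c <= 0:
        return []
    width = hi - lo
    out = []
    for i in range(1, c + 1):
        t = lo + (i - 0.5) / c * width
        if np.any(np.abs(grid - t) < 1e-9):
            t -= min(1e-3, width / (4.0 * c))
        out.append(t)
    return out


@dataclass
class _SegmentResult:
    events: list[tuple[float, int]] = field(default_factory=list)
    censor_times: list[float] = field(default_factory=list)
    n_end: int = 0
    shat_end: float = 1.0
    d_total: int = 0


def _simulate_segment(steps, censor_times, n0: int, shat0: float) -> _SegmentResult:
    """Walk one interval: digitized steps (time, S_target) interleaved with
    candidate censoring times; events from KM probability ratios."""
    timeline = [(t, 1, s) for t, s in steps] + [(t, 0, None) for t in censor_times]
    timeline.sort(key=lambda x: (x[0], x[1]))  # censor before step at equal time
    res = _SegmentResult(n_end=n0, shat_end=shat0)
    n, shat = n0, shat0
    for t, kind, starget in timeline:
        if kind == 0:
            if n > 0:
                n -= 1
                res.censor_times.append(t)
        else:
            if n <= 0 or shat <= 0:
                continue
            ratio = min(max(starget / shat, 0.0), 1.0)
            d = _round_half_even(n * (1.0 - ratio))
            d = max(0, min(d, n))
            if d > 0:
                shat *= 1.0 - d / n
                n -= d
                res.events.append((t, d))
                res.d_total += d
    res.n_end, res.shat_end = n, shat
    return res


def reconstruct_ipd(curve: DigitizedCurve) -> IPDSet:
    """Map a digitized curve back to approximate individual patient data.

    Returns exactly ``n_at_risk[0]`` records; raises
    :class:`ReconstructionInfeasibleError` when no non-negative censoring
    count can reproduce a published number at risk.
    """
    curve.validate()
    grid_t = curve.times
    grid_s = curve.surv_probs
    rt = curve.risk_times
    nar = curve.n_at_risk
    if rt.size < 1:
        raise InvalidCurveError(f"{curve._tag}: empty risk table")

    all_events: list[tuple[float, int]] = []
    all_censors: list[float] = []
    n_cur = int(nar[0])
    shat = 1.0
    n0 = n_cur

    # steps (t, S) for t > 0.  A drop recorded at a risk-table time is
    # produced by events occurring up to (and including) that time, before
    # the published risk count applies, so interval j owns (R_j, R_{j+1}].
    steps_all = [(float(t), float(s)) for t, s in zip(grid_t[1:], grid_s[1:])]

    def steps_in(lo, hi):
        return [(t, s) for t, s in steps_all if lo + 1e-9 < t <= hi + 1e-9]

    for j in range(rt.size - 1):
        lo, hi = float(rt[j]), float(rt[j + 1])
        n_pub = int(nar[j + 1])
        steps = steps_in(lo, hi)
        # initial guess for the censoring count from the KM-implied events
        probe = _simulate_segment(steps, [], n_cur, shat)
        c_est = max(0, min(n_cur, n_cur - probe.d_total - n_pub))

        def run(c):
            return _simulate_segment(
                steps, _censor_positions(lo, hi, c, grid_t), n_cur, shat
            )

        chosen = None
        tried: dict[int, _SegmentResult] = {}
        for radius in range(0, n_cur + 1):
            cands = [c_est - radius] if radius == 0 else [c_est - radius, c_est + radius]
            for c in cands:
                if 0 <= c <= n_cur and c not in tried:
                    seg = run(c)
                    tried[c] = seg
                    if seg.n_end == n_pub:
                        chosen = (c, seg)
                        break
            if chosen is not None:
                break
            if c_est - radius < 0 and c_est + radius > n_cur:
                break
        if chosen is None:
            # rounding can make n_end skip the published value; repair by
            # appending extra censorings at the interval end (after all
            # steps), which lowers n_end without touching event counts
            surplus = [(c, seg) for c, seg in tried.items() if seg.n_end > n_pub]
            if not surplus:
                raise ReconstructionInfeasibleError(
                    f"{curve._tag}: published number at risk {n_pub} at month "
                    f"{hi:g} is unattainable for any censoring count",
                    interval=(lo, hi),
                )
            c, seg = min(surplus, key=lambda cs: (cs[1].n_end, cs[0]))
            extra = seg.n_end - n_pub
            # appended after every step (no re-simulation), so event counts
            # are untouched; recorded at the interval end time
            pad = [hi] * extra
            seg = _SegmentResult(
                events=seg.events, censor_times=seg.censor_times + pad,
                n_end=n_pub, shat_end=seg.shat_end, d_total=seg.d_total,
            )
            chosen = (c + extra, seg)

        _, seg = chosen
        all_events.extend(seg.events)
        all_censors.extend(seg.censor_times)
        n_cur, shat = seg.n_end, seg.shat_end

    # residual tail beyond the last risk-table time
    t_last = float(grid_t[-1])
    lo = float(rt[-1])
    tail_steps = steps_in(lo, t_last)
    d_so_far = sum(d for _, d in all_events)
    if curve.total_events is not None and tail_steps:
        target = curve.total_events - d_so_far
        best = None
        for c in range(0, n_cur + 1):
            seg = _simulate_segment(
                tail_steps, _censor_positions(lo, t_last, c, grid_t), n_cur, shat
            )
            diff = abs(seg.d_total - target)
            if best is None or diff < best[0]:
                best = (diff, c, seg)
            if diff == 0:
                break
        _, _, seg = best
    else:
        seg = _simulate_segment(tail_steps, [], n_cur, shat)
    all_events.extend(seg.events)
    all_censors.extend(seg.censor_times)
    n_cur = seg.n_end

    # anyone still at risk is administratively censored at the last
    # digitized time
    all_censors.extend([t_last] * n_cur)

    times = []
    events = []
    for t, d in all_events:
        times.extend([t] * d)
        events.extend([1] * d)
    times.extend(all_censors)
    events.extend([0] * len(all_censors))
    ipd = IPDSet(time=np.array(times), event=np.array(events),
                 arm=curve.arm, endpoint=curve.endpoint)
    assert ipd.n == n0, "reconstruction must conserve subjects"
    return ipd
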