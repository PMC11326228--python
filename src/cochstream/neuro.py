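"""Neural effect-time analysis chain.

Mirrors the experimental pipeline used with multi-unit recordings from the
cochlear nucleus during round-window drug delivery: waveforms are
Teager-energy transformed to emphasize spiking, averaged per stimulus
segment, reduced to per-sequence *driven responses* (CF-tone response minus
spontaneous activity in the silent pause), normalized to the pre-application
baseline, and scanned for the effect time t_E — the first sustained drop
below 75% of baseline.  Effect times from many locations are normalized by
a one-parameter 1-D diffusion trend t = a x^2 and expressed in dB
(20 log10(t_E / t_Trend)) so that delivery speed can be compared across
locations and acoustic conditions with Welch t-tests.  A swept-tone DPOAE
level analysis (least-squares sinusoid fits in sliding Hann windows, with
an even/odd-presentation null for the noise floor) verifies outer-hair-cell
function.

The stimulus schedule is the repeating 57.2-s sequence of the recording
protocol: 48 noise pips, one silent pause and three CF tone pips, each
1.1 s long (52 segments per sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .travelwave import PlaceFrequencyMap

__all__ = [
    "SEQUENCE_SECONDS",
    "SEGMENT_SECONDS",
    "SEGMENTS_PER_SEQUENCE",
    "NeuralRecording",
    "ResponseTimeCourse",
    "EffectTimeEstimate",
    "TrendModel",
    "GroupComparison",
    "teager_energy",
    "segment_responses",
    "driven_response_curve",
    "effect_time",
    "fit_diffusion_trend",
    "effect_time_db",
    "effect_time_from_db",
    "compare_groups",
    "dpoae_level_sweep",
    "make_schedule",
]

SEGMENT_SECONDS = 1.1
N_NOISE = 48
N_TONES = 3
SEGMENTS_PER_SEQUENCE = N_NOISE + 1 + N_TONES          # 52
SEQUENCE_SECONDS = SEGMENTS_PER_SEQUENCE * SEGMENT_SECONDS  # 57.2


def make_schedule(n_sequences: int, channel_cfs_khz: np.ndarray,
                  t0: float = 0.0) -> pd.DataFrame:
    """Segment table for ``n_sequences`` repetitions of the protocol.

    Columns: sequence, segment, label (``noise``/``pause``/``tone``),
    tone_cf_khz (NaN except tone segments), t_start, t_end (s).  The three
    tone pips probe the channels' CFs in order.
    """
    cfs = np.asarray(channel_cfs_khz, dtype=float)
    if cfs.size != N_TONES:
        raise ValueError(f"protocol probes exactly {N_TONES} CF channels")
    rows = []
    for s in range(n_sequences):
        base = t0 + s * SEQUENCE_SECONDS
        for k in range(SEGMENTS_PER_SEQUENCE):
            if k < N_NOISE:
                label, cf = "noise", np.nan
            elif k == N_NOISE:
                label, cf = "pause", np.nan
            else:
                label, cf = "tone", cfs[k - N_NOISE - 1]
            rows.append((s, k, label, cf,
                         base + k * SEGMENT_SECONDS,
                         base + (k + 1) * SEGMENT_SECONDS))
    return pd.DataFrame(rows, columns=["sequence", "segment", "label",
                                       "tone_cf_khz", "t_start", "t_end"])


@dataclass
class NeuralRecording:
    """Multi-channel sampled recording plus its stimulus schedule.

    ``waveform`` has shape (n_channels, n_samples); ``fs`` is the sampling
    rate in Hz; ``channel_cfs_khz`` the per-channel characteristic
    frequencies; ``schedule`` a segment table from :func:`make_schedule`;
    ``t_drug`` the drug-application time in s (time axis of the schedule).
    """

    waveform: np.ndarray
    fs: float
    channel_cfs_khz: np.ndarray
    schedule: pd.DataFrame
    t_drug: float = 0.0

    def __post_init__(self) -> None:
        self.waveform = np.atleast_2d(np.asarray(self.waveform))
        self.channel_cfs_khz = np.asarray(self.channel_cfs_khz, dtype=float)
        if self.waveform.shape[0] != self.channel_cfs_khz.size:
            raise ValueError("one CF per waveform channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.waveform.shape[1] / self.fs


@dataclass
class ResponseTimeCourse:
    """Per-channel driven response versus sequence time."""

    t: np.ndarray              # s, sequence (pause) midpoints
    driven: np.ndarray         # raw driven amplitude (Teager units)
    normalized: np.ndarray     # driven / baseline
    baseline: float
    cf_khz: float
    t_drug: float


@dataclass
class EffectTimeEstimate:
    """t_E for one channel with audit flags."""

    t_e: float | None          # s after drug application; None if not crossed
    cf_khz: float
    x_m: float | None          # place via the CF map, if one was supplied
    crossed: bool
    bimodal: bool              # curve re-rose above criterion after crossing
    criterion: float


@dataclass
class TrendModel:
    """One-parameter 1-D diffusion trend t_Trend(x) = a x^2.

    ``a`` is in s/m^2; given the threshold fraction, the implied effective
    diffusivity is D_eff = 1 / (4 a erfcinv(f_thr)^2).
    """

    a: float
    log_resid_rms: float
    n: int

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** 2

    def d_eff(self, f_thr: float = 0.01) -> float:
        from scipy.special import erfcinv
        return 1.0 / (4.0 * self.a * float(erfcinv(f_thr)) ** 2)


@dataclass
class GroupComparison:
    t_stat: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    ci95_a: tuple
    ci95_b: tuple
    n_a: int
    n_b: int


def teager_energy(x: np.ndarray) -> np.ndarray:
    """Discrete Teager energy Psi[n] = x[n]^2 - x[n-1] x[n+1].

    Emphasizes high-frequency, high-amplitude activity (spikes).  The two
    end samples are dropped.  For a sinusoid A sin(Omega n + phi) the
    operator returns the constant A^2 sin^2(Omega).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D signal with at least 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def segment_responses(rec: NeuralRecording) -> pd.DataFrame:
    """Mean Teager energy per schedule segment and channel.

    Returns a tidy frame with one row per (channel, segment): columns
    ``channel, cf_khz, sequence, segment, label, tone_cf_khz, t_mid,
    teager_mean``.  Sequences extending past the end of the recording are
    excluded; their indices are listed in ``frame.attrs["dropped_sequences"]``.
    """
    sched = rec.schedule
    if rec.duration < SEQUENCE_SECONDS - 1e-9:
        raise ValueError("recording shorter than one stimulus sequence")
    t_origin = float(sched["t_start"].min())
    t_end_rec = t_origin + rec.duration
    full = sched.groupby("sequence")["t_end"].max() <= t_end_rec + 1e-9
    kept = set(full[full].index)
    dropped = sorted(set(sched["sequence"]) - kept)
    rows = []
    for ch in range(rec.waveform.shape[0]):
        psi = teager_energy(rec.waveform[ch])
        for seg in sched.itertuples(index=False):
            if seg.sequence not in kept:
                continue
            i0 = int(round((seg.t_start - t_origin) * rec.fs))
            i1 = int(round((seg.t_end - t_origin) * rec.fs))
            # Teager trace is offset by one sample relative to the waveform
            chunk = psi[max(i0 - 1, 0):i1 - 1]
            rows.append((ch, rec.channel_cfs_khz[ch], seg.sequence, seg.segment,
                         seg.label, seg.tone_cf_khz,
                         0.5 * (seg.t_start + seg.t_end), float(chunk.mean())))
    out = pd.DataFrame(rows, columns=["channel", "cf_khz", "sequence", "segment",
                                      "label", "tone_cf_khz", "t_mid",
                                      "teager_mean"])
    out.attrs["dropped_sequences"] = dropped
    return out


def driven_response_curve(segments: pd.DataFrame, t_drug: float = 0.0,
                          smooth: bool = False) -> dict[int, ResponseTimeCourse]:
    """Per-sequence driven responses, normalized to the pre-drug baseline.

    driven = (mean Teager of the channel's own CF tone pip) - (mean Teager
    of the silent pause) per sequence.  The baseline is the mean driven
    value over all sequences preceding ``t_drug``; at least one such
    sequence is required.  ``smooth`` applies an optional 3-sequence moving
    average to the normalized curve (off by default).
    """
    out: dict[int, ResponseTimeCourse] = {}
    for ch, g in segments.groupby("channel"):
        cf = float(g["cf_khz"].iloc[0])
        pause = g[g["label"] == "pause"].set_index("sequence")["teager_mean"]
        tones = g[(g["label"] == "tone") & np.isclose(g["tone_cf_khz"], cf)]
        tone = tones.set_index("sequence")["teager_mean"]
        seqs = pause.index.intersection(tone.index).sort_values()
        if seqs.empty:
            raise ValueError(f"channel {ch}: no sequences with pause and CF tone")
        driven = (tone.loc[seqs] - pause.loc[seqs]).to_numpy()
        t_mid = g[g["label"] == "pause"].set_index("sequence")["t_mid"] \
            .loc[seqs].to_numpy()
        pre = t_mid < t_drug
        if not pre.any():
            raise ValueError(
                f"channel {ch}: no pre-application sequences to normalize by")
        baseline = float(driven[pre].mean())
        if baseline <= 0:
            raise ValueError(f"channel {ch}: non-positive baseline")
        norm = driven / baseline
        if smooth:
            norm = np.convolve(norm, np.ones(3) / 3.0, mode="same")
        out[int(ch)] = ResponseTimeCourse(
            t=t_mid, driven=driven, normalized=norm, baseline=baseline,
            cf_khz=cf, t_drug=t_drug)
    return out


def effect_time(curve: ResponseTimeCourse, criterion: float = 0.75,
                pf_map: PlaceFrequencyMap | None = None,
                sustain: int = 2, rebound: float = 0.1) -> EffectTimeEstimate:
    """First sustained drop of the normalized response below ``criterion``.

    A crossing counts when the curve stays below the criterion for at least
    ``sustain`` consecutive sequences after the drug time; t_E is linearly
    interpolated between the last above-criterion sample and the first of
    the sustained run, and reported relative to the drug-application time.
    A later rise back above ``criterion + rebound`` sets the bimodal flag
    (broad, two-step decays occur toward low-CF locations).  A curve that
    never crosses is returned with ``crossed=False`` and no numeric t_E.
    """
    post = curve.t >= curve.t_drug
    if post.sum() < 2:
        raise ValueError("need at least two post-application sequences")
    t = curve.t[post]
    y = curve.normalized[post]
    below = y < criterion
    idx = None
    run = 0
    need = min(sustain, below.size)
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= need:
            idx = i - run + 1
            break
    if idx is None:
        return EffectTimeEstimate(t_e=None, cf_khz=curve.cf_khz,
                                  x_m=_place(pf_map, curve.cf_khz),
                                  crossed=False, bimodal=False,
                                  criterion=criterion)
    if idx == 0:
        t_cross = t[0]
    else:
        y0, y1 = y[idx - 1], y[idx]
        frac = (y0 - criterion) / (y0 - y1) if y0 != y1 else 1.0
        t_cross = t[idx - 1] + frac * (t[idx] - t[idx - 1])
    bimodal = bool(np.any(y[idx:] > criterion + rebound))
    return EffectTimeEstimate(t_e=float(t_cross - curve.t_drug),
                              cf_khz=curve.cf_khz,
                              x_m=_place(pf_map, curve.cf_khz),
                              crossed=True, bimodal=bimodal,
                              criterion=criterion)


def _place(pf_map: PlaceFrequencyMap | None, cf_khz: float) -> float | None:
    return None if pf_map is None else float(pf_map.cf_to_place(cf_khz))


def fit_diffusion_trend(effect_times: np.ndarray,
                        places: np.ndarray) -> TrendModel:
    """Least-squares fit of the 1-D diffusion scaling t = a x^2 in log space.

    With the exponent fixed at 2, the log-space least-squares solution is
    the geometric mean of t / x^2 — consistent with comparing effect times
    in dB.  Requires >= 3 points that are not all at the same place.
    """
    t = np.asarray(effect_times, dtype=float)
    x = np.asarray(places, dtype=float)
    if t.size != x.size:
        raise ValueError("effect_times and places must match in length")
    if t.size < 3:
        raise ValueError("need at least 3 (x, t_E) points")
    if np.unique(x).size < 2:
        raise ValueError("places must not be all identical")
    if np.any(t <= 0) or np.any(x <= 0):
        raise ValueError("effect times and places must be positive")
    logr = np.log(t) - 2.0 * np.log(x)
    a = float(np.exp(logr.mean()))
    resid = logr - logr.mean()
    return TrendModel(a=a, log_resid_rms=float(np.sqrt(np.mean(resid**2))),
                      n=t.size)


def effect_time_db(t_e: float | np.ndarray,
                   t_trend: float | np.ndarray) -> float | np.ndarray:
    """Effect time relative to the diffusion trend: 20 log10(t_E / t_Trend).

    Negative values mean faster-than-diffusion delivery.
    """
    t_e = np.asarray(t_e, dtype=float)
    t_trend = np.asarray(t_trend, dtype=float)
    if np.any(t_e <= 0) or np.any(t_trend <= 0):
        raise ValueError("t_E and t_Trend must be positive")
    out = 20.0 * np.log10(t_e / t_trend)
    return float(out) if out.ndim == 0 else out


def effect_time_from_db(db: float | np.ndarray,
                        t_trend: float | np.ndarray) -> float | np.ndarray:
    """Exact inverse of :func:`effect_time_db`: t_E = t_Trend 10^(dB/20)."""
    return np.asarray(t_trend, dtype=float) * 10.0 ** (np.asarray(db, dtype=float) / 20.0)


def compare_groups(db_a: np.ndarray, db_b: np.ndarray) -> GroupComparison:
    """Two-tailed Welch t-test between dB effect times of two conditions,
    with group means and 95% confidence intervals."""
    a = np.asarray(db_a, dtype=float)
    b = np.asarray(db_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    def ci(v):
        sem = stats.sem(v)
        h = sem * stats.t.ppf(0.975, v.size - 1)
        return (float(v.mean() - h), float(v.mean() + h))
    return GroupComparison(
        t_stat=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        ci95_a=ci(a), ci95_b=ci(b), n_a=a.size, n_b=b.size)


def dpoae_level_sweep(mic_waveforms: np.ndarray, fs: float,
                      f2_start: float = 500.0, f2_end: float = 10000.0,
                      sweep_seconds: float = 4.0, ratio: float = 1.25,
                      window_seconds: float = 0.1,
                      step_seconds: float = 0.02,
                      ref: float = 20e-6) -> pd.DataFrame:
    """Swept-tone DPOAE level at 2 f1 - f2 with an even/odd noise floor.

    ``mic_waveforms`` has shape (n_presentations, n_samples) for a linear
    upward f2 sweep (f1 = f2 / ratio).  In each Hann window the averaged
    response is least-squares fitted with a quadrature pair following the
    instantaneous distortion-product phase; the same analysis applied to
    half the difference of even- and odd-presentation averages estimates
    the noise floor.  Levels are dB re ``ref`` (RMS).

    Returns a frame with columns ``t, f2_hz, fdp_hz, level_db,
    noise_floor_db`` (noise floor NaN when fewer than 2 presentations).
    """
    w = np.atleast_2d(np.asarray(mic_waveforms, dtype=float))
    n_pres, n = w.shape
    mean = w.mean(axis=0)
    null = None
    if n_pres >= 2:
        null = 0.5 * (w[0::2].mean(axis=0) - w[1::2].mean(axis=0))
    tseg = np.arange(n) / fs
    rate = (f2_end - f2_start) / sweep_seconds
    # 2 f1 - f2 = (2/ratio - 1) f2;  phase = 2 pi * integral of f_dp dt
    fac = 2.0 / ratio - 1.0
    fdp = fac * (f2_start + rate * tseg)
    phase = 2.0 * np.pi * fac * (f2_start * tseg + 0.5 * rate * tseg**2)
    cosp, sinp = np.cos(phase), np.sin(phase)
    nwin = int(round(window_seconds * fs))
    step = int(round(step_seconds * fs))
    hann = np.hanning(nwin)
    rows = []
    for i0 in range(0, n - nwin + 1, step):
        sl = slice(i0, i0 + nwin)
        A = np.stack([cosp[sl] * hann, sinp[sl] * hann], axis=1)

        def fit_level(sig):
            coef, *_ = np.linalg.lstsq(A, sig[sl] * hann, rcond=None)
            amp = float(np.hypot(*coef))
            return 20.0 * np.log10(max(amp / np.sqrt(2.0), 1e-300) / ref)

        mid = i0 + nwin // 2
        rows.append((mid / fs, f2_start + rate * mid / fs, fdp[mid],
                     fit_level(mean),
                     fit_level(null) if null is not None else np.nan))
    return pd.DataFrame(rows, columns=["t", "f2_hz", "fdp_hz", "level_db",
                                       "noise_floor_db"])
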