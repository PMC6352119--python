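"""Beat segmentation and landmark delineation on PPG, VPG and APG.

Landmarks (per beat, sample indices, ``None`` when absent):

- PPG: O (onset), S (systolic peak), N (dicrotic notch), D (diastolic peak)
- VPG: w, x, y, z — the alternating max/min/max/min after the upstroke
- APG: a, b, c, d, e — the alternating max/min/max/min/max

Missing landmarks propagate as missing values downstream, never as zeros.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .types import BeatFiducials, WaveformSet

# fraction of the waveform's range an extremum must stand out by; filters
# residual quantization/noise ripple without touching genuine small waves
_PROMINENCE_FRAC = 0.01

# refractory separation between successive upslope peaks (s)
_MIN_BEAT_SEP = 0.3


def _extrema(x: np.ndarray, kind: str) -> np.ndarray:
    """Indices of interior local maxima/minima with non-trivial prominence."""
    rng = float(np.ptp(x))
    if rng == 0:
        return np.asarray([], dtype=int)
    sig = x if kind == "max" else -x
    idx, _ = find_peaks(sig, prominence=_PROMINENCE_FRAC * rng)
    return idx


def segment_beats(wave: WaveformSet, *, upslope_frac: float = 0.5
                  ) -> list[tuple[int, int]]:
    """Half-open (start, end) boundaries of complete beats.

    Beat anchors are VPG (upslope) peaks exceeding ``upslope_frac`` times the
    record's median genuine upslope-peak height, separated by a refractory
    period; each onset is the PPG local minimum immediately preceding its
    anchor.  Partial leading/trailing beats are discarded.
    """
    ppg, vpg = wave.ppg, wave.vpg
    if len(ppg) < wave.fs:  # need >= 1 s
        return []
    sep = int(_MIN_BEAT_SEP * wave.fs)
    cand, _ = find_peaks(vpg, height=0.0, distance=sep)
    if cand.size == 0:
        return []
    # genuine upslope peaks: within striking distance of the tallest one
    tall = cand[vpg[cand] > 0.5 * vpg[cand].max()]
    med = float(np.median(vpg[tall]))
    strong, _ = find_peaks(vpg, height=upslope_frac * med, distance=sep)
    if strong.size == 0:
        return []
    minima = _extrema(ppg, "min")
    onsets: list[int] = []
    for pk in strong:
        before = minima[minima < pk]
        if before.size:
            onset = int(before[-1])
            if not onsets or onset != onsets[-1]:
                onsets.append(onset)
    beats = [(onsets[i], onsets[i + 1]) for i in range(len(onsets) - 1)]
    return [(s, e) for s, e in beats if e > s]


def detect_vpg_points(wave: WaveformSet, beat: tuple[int, int]
                      ) -> tuple[Optional[int], ...]:
    """(t_w, t_x, t_y, t_z): global VPG max then alternating min/max/min."""
    s, e = beat
    seg = wave.vpg[s:e]
    if seg.size == 0:
        return (None, None, None, None)
    t_w = s + int(np.argmax(seg))
    maxima = _extrema(wave.vpg, "max")
    minima = _extrema(wave.vpg, "min")
    t_x = _first_after(minima, t_w, e)
    t_y = _first_after(maxima, t_x, e) if t_x is not None else None
    t_z = _first_after(minima, t_y, e) if t_y is not None else None
    return (t_w, t_x, t_y, t_z)


def detect_apg_points(wave: WaveformSet, beat: tuple[int, int]
                      ) -> tuple[Optional[int], ...]:
    """(t_a..t_e): first APG max, then alternating extrema before 80% of beat."""
    s, e = beat
    maxima = _extrema(wave.apg, "max")
    minima = _extrema(wave.apg, "min")
    limit = s + int(0.8 * (e - s))
    # guard band: skip the first ~10 ms, where the onset corner contaminates
    # the second derivative
    guard = s + max(1, int(0.010 * wave.fs))
    t_a = _first_after(maxima, guard, e, inclusive=True)
    t_b = _first_after(minima, t_a, e) if t_a is not None else None
    t_c = _first_after(maxima, t_b, limit) if t_b is not None else None
    t_d = _first_after(minima, t_c, limit) if t_c is not None else None
    t_e = _first_after(maxima, t_d, limit) if t_d is not None else None
    return (t_a, t_b, t_c, t_d, t_e)


def detect_ppg_points(wave: WaveformSet, beat: tuple[int, int],
                      apg_points: tuple[Optional[int], ...] | None = None
                      ) -> tuple[Optional[int], ...]:
    """(t_O, t_S, t_N, t_D).

    N is the first PPG local minimum after S; for notchless beats it falls
    back to the APG e-wave time.  D is the first PPG local maximum after N.
    """
    s, e = beat
    t_O = s
    seg = wave.ppg[s:e]
    if seg.size == 0:
        return (t_O, None, None, None)
    t_S = s + int(np.argmax(seg))
    minima = _extrema(wave.ppg, "min")
    maxima = _extrema(wave.ppg, "max")
    t_N = _first_after(minima, t_S, e)
    if t_N is None and apg_points is not None:
        t_e_wave = apg_points[4]
        if t_e_wave is not None and t_S < t_e_wave < e:
            t_N = t_e_wave
    t_D = _first_after(maxima, t_N, e) if t_N is not None else None
    return (t_O, t_S, t_N, t_D)


def _first_after(indices: np.ndarray, after: Optional[int], before: int,
                 inclusive: bool = False) -> Optional[int]:
    if after is None:
        return None
    lo = after if inclusive else after + 1
    cand = indices[(indices >= lo) & (indices < before)]
    return int(cand[0]) if cand.size else None


def delineate_beat(wave: WaveformSet, beat: tuple[int, int]) -> BeatFiducials:
    """All landmarks of one beat."""
    apg = detect_apg_points(wave, beat)
    vpg = detect_vpg_points(wave, beat)
    ppg = detect_ppg_points(wave, beat, apg)
    s, e = beat
    return BeatFiducials(
        beat_start=s, beat_end=e,
        t_O=ppg[0], t_S=ppg[1], t_N=ppg[2], t_D=ppg[3],
        t_w=vpg[0], t_x=vpg[1], t_y=vpg[2], t_z=vpg[3],
        t_a=apg[0], t_b=apg[1], t_c=apg[2], t_d=apg[3], t_e=apg[4],
    )


def delineate(wave: WaveformSet) -> list[BeatFiducials]:
    """Segment the record and delineate every complete beat."""
    return [delineate_beat(wave, b) for b in segment_beats(wave)]


def project(wave: WaveformSet, landmark_time: Optional[int], native_level: int,
            shift: int) -> float:
    """Value of the waveform ``shift`` derivative levels away at a landmark time."""
    level = native_level + shift
    if not 0 <= level <= 3:
        raise ValueError(f"projected level {level} outside 0..3")
    if landmark_time is None:
        return float("nan")
    return float(wave.level(level)[landmark_time])


def fiducials_frame(beats: Sequence[BeatFiducials]):
    """Rows of landmark indices, one per beat (for the CSV writer)."""
    import pandas as pd

    cols = ["t_O", "t_S", "t_N", "t_D", "t_w", "t_x", "t_y", "t_z",
            "t_a", "t_b", "t_c", "t_d", "t_e"]
    rows = []
    for i, bf in enumerate(beats):
        row = {"beat": i}
        row.update({c: getattr(bf, c) for c in cols})
        rows.append(row)
    return pd.DataFrame(rows, columns=["beat"] + cols)
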