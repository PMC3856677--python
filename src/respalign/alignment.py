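"""Listener–reader temporal alignment: the posI statistic and its null.

Each listener inhalation onset is positioned inside the reader breathing
cycle that contains it: posI = (t − onset_i) / (onset_{i+1} − onset_i),
a fraction in [0, 1) where 0 marks coincidence with a reader inhalation
onset.  Two periodic signals align occasionally by chance, so the
original listener–reader pairing is compared against surrogate pairings
in which each listener trial is re-associated with the reader's recording
of a *different* text in the same condition (a derangement, so no trial
keeps its own reader).  Distributions are compared with two-sample
Kolmogorov–Smirnov tests; pooled cycles ignore within-listener dependence
(a deliberate caveat, documented in the methods note).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import BreathingCycle, ContractError, KSResult, LabelError, ParameterError

__all__ = [
    "align_to_speech_onset",
    "shift_cycles",
    "compute_posI",
    "derangement",
    "random_association",
    "posI_observations",
    "ks_two_sample",
    "reflected_kde",
    "posI_mode",
    "posI_report",
]


def shift_cycles(cycles: list[BreathingCycle], dt: float) -> list[BreathingCycle]:
    """Shift all cycle landmarks by ``dt`` seconds."""
    from dataclasses import replace

    return [
        replace(
            c,
            onset_t=c.onset_t + dt,
            inhal_offset_t=c.inhal_offset_t + dt,
            next_onset_t=c.next_onset_t + dt,
        )
        for c in cycles
    ]


def align_to_speech_onset(
    listener_cycles: list[BreathingCycle],
    reader_cycles: list[BreathingCycle],
    listener_onset_s: float | None,
    reader_onset_s: float | None,
) -> tuple[list[BreathingCycle], list[BreathingCycle]]:
    """Re-express both cycle sets with t = 0 at the trial's speech onset.

    Each side is shifted by its own label (the playback and the original
    reading need not start at the same recording time).
    """
    if listener_onset_s is None or reader_onset_s is None:
        raise LabelError("speech-onset label required on both trials")
    return (
        shift_cycles(listener_cycles, -listener_onset_s),
        shift_cycles(reader_cycles, -reader_onset_s),
    )


def compute_posI(
    listener_onsets: np.ndarray | list[float],
    reader_onsets: np.ndarray | list[float],
) -> pd.DataFrame:
    """Fractional position of each listener onset in its reader cycle.

    Half-open convention: onset t maps to reader cycle i when
    onset_i <= t < onset_{i+1}; onsets before the first or at/after the
    last reader onset are dropped.  Returns columns ``posI``,
    ``listener_onset_t``, ``reader_cycle`` and ``first_cycle`` (the first
    listener onset of the trial).
    """
    r = np.asarray(reader_onsets, dtype=float)
    if len(r) < 2:
        raise ContractError("need at least two reader onsets (one cycle)")
    if not (np.diff(r) > 0).all():
        raise ContractError("reader onsets must be strictly increasing")
    t = np.asarray(listener_onsets, dtype=float)
    first_t = t[0] if len(t) else np.nan
    idx = np.searchsorted(r, t, side="right") - 1
    ok = (idx >= 0) & (idx < len(r) - 1)
    t, idx = t[ok], idx[ok]
    pos = (t - r[idx]) / (r[idx + 1] - r[idx])
    return pd.DataFrame(
        dict(
            posI=pos,
            listener_onset_t=t,
            reader_cycle=idx,
            first_cycle=(t == first_t),
        )
    )


def derangement(items: list, rng: np.random.Generator) -> list:
    """Uniform random derangement (no element maps to itself), by rejection."""
    if len(items) < 2:
        raise ParameterError("derangement needs at least two items")
    idx = np.arange(len(items))
    while True:
        perm = rng.permutation(len(items))
        if not np.any(perm == idx):
            return [items[i] for i in perm]


def posI_observations(
    design: pd.DataFrame,
    listener_onsets: dict[tuple[str, int], np.ndarray],
    reader_onsets: dict[tuple[str, str, str], np.ndarray],
    pairing: str = "original",
    text_map: dict[tuple[str, int], str] | None = None,
    draw: int | None = None,
) -> pd.DataFrame:
    """posI table for one listener→reader trial mapping.

    ``listener_onsets`` are aligned listener inhalation onsets keyed by
    (listener, trial_index); ``reader_onsets`` aligned reader onsets keyed
    by (reader, text, condition).  ``text_map`` overrides which reader
    text a listener trial is paired with (surrogate pairings).
    """
    frames = []
    for row in design.itertuples(index=False):
        key = (row.listener, int(row.trial_index))
        if key not in listener_onsets:
            continue
        text = text_map.get(key, row.text) if text_map else row.text
        r_on = reader_onsets[(row.reader, text, row.condition)]
        obs = compute_posI(listener_onsets[key], r_on)
        obs["listener_id"] = row.listener
        obs["trial_index"] = int(row.trial_index)
        obs["text_id"] = text
        obs["own_text"] = row.text
        obs["condition"] = row.condition
        obs["reader"] = row.reader
        obs["pairing"] = pairing
        obs["surrogate_draw"] = draw if draw is not None else pd.NA
        frames.append(obs)
    if not frames:
        return pd.DataFrame(
            columns=[
                "posI", "listener_onset_t", "reader_cycle", "first_cycle",
                "listener_id", "trial_index", "text_id", "own_text",
                "condition", "reader", "pairing", "surrogate_draw",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def random_association(
    design: pd.DataFrame,
    listener_onsets: dict[tuple[str, int], np.ndarray],
    reader_onsets: dict[tuple[str, str, str], np.ndarray],
    seed: int = 0,
    n_draws: int = 1,
) -> pd.DataFrame:
    """Surrogate posI by deranging texts within condition, per listener.

    Each draw re-pairs every listener trial with the same reader reading a
    different text of the same condition; listener cycles are untouched,
    so the surrogate preserves the listener-cycle multiset exactly and
    differs only on the reader side.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5A5A])
    frames = []
    for d in range(n_draws):
        text_map: dict[tuple[str, int], str] = {}
        for (listener, condition), grp in design.groupby(["listener", "condition"]):
            texts = list(grp["text"])
            if len(set(texts)) < 2:
                raise ParameterError(
                    f"listener {listener}, condition {condition}: need >=2 texts "
                    "for a surrogate pairing"
                )
            deranged = derangement(texts, rng)
            for trial_index, new_text in zip(grp["trial_index"], deranged):
                text_map[(listener, int(trial_index))] = new_text
        frames.append(
            posI_observations(
                design, listener_onsets, reader_onsets,
                pairing="surrogate", text_map=text_map, draw=d,
            )
        )
    return pd.concat(frames, ignore_index=True)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample KS test: D = sup |ECDF_a − ECDF_b|.

    Exact p for small samples, asymptotic otherwise (scipy's auto rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ContractError("KS test requires non-empty samples")
    res = sstats.ks_2samp(a, b, method="auto")
    return KSResult(D=float(res.statistic), p=float(res.pvalue), n1=len(a), n2=len(b))


def reflected_kde(
    x: np.ndarray, grid: np.ndarray | None = None, bw: str | float = "silverman"
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on [0, 1] with reflection at both boundaries.

    posI is a phase fraction, so mass near 0/1 would otherwise leak out of
    the support.  Diagnostic/plotting only — never inference.
    """
    x = np.asarray(x, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    augmented = np.concatenate([x, -x, 2.0 - x])
    # bandwidth from the ORIGINAL sample: the reflected copies would
    # otherwise inflate the variance and oversmooth concentrated phases
    if bw == "silverman":
        h = np.std(x, ddof=1) * (3.0 * len(x) / 4.0) ** (-0.2)
    else:
        h = float(bw) * np.std(x, ddof=1)
    h = max(h, 1e-3)
    kde = sstats.gaussian_kde(augmented, bw_method=h / np.std(augmented, ddof=1))
    dens = 3.0 * kde(grid)  # reflection triples the mass; renormalize
    return grid, dens


def posI_mode(x: np.ndarray) -> float:
    """Location of the posI density maximum (reflected-KDE argmax)."""
    grid, dens = reflected_kde(np.asarray(x, dtype=float))
    return float(grid[np.argmax(dens)])


def posI_report(
    observations: pd.DataFrame,
    subset: str = "all",
    by: tuple[str, ...] = ("condition", "reader"),
    bins: int = 20,
) -> pd.DataFrame:
    """Per-stratum original-vs-surrogate comparison of posI distributions.

    For each stratum (default condition × reader): sample sizes, density
    mode of the original pairing, and KS(original, surrogate).  ``subset``
    restricts to the first listener cycle of each trial (``"first_cycle"``)
    or uses all cycles (``"all"``).  Strata with no original observations
    are omitted with a warning; the KS entry is NaN when either side has
    fewer than 2 values.
    """
    if subset not in ("all", "first_cycle"):
        raise ParameterError(f"unknown subset {subset!r}")
    obs = observations
    if subset == "first_cycle":
        obs = obs[obs["first_cycle"]]
    rows = []
    for keys, grp in obs.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        orig = grp.loc[grp["pairing"] == "original", "posI"].to_numpy()
        surr = grp.loc[grp["pairing"] == "surrogate", "posI"].to_numpy()
        if len(orig) == 0:
            warnings.warn(f"stratum {keys}: no original observations, omitted")
            continue
        hist, edges = np.histogram(orig, bins=bins, range=(0.0, 1.0))
        row = dict(zip(by, keys))
        row.update(
            subset=subset,
            n_original=len(orig),
            n_surrogate=len(surr),
            mode=posI_mode(orig) if len(orig) >= 2 else float(orig[0]),
            hist=",".join(str(int(h)) for h in hist),
        )
        if len(orig) >= 2 and len(surr) >= 2:
            ks = ks_two_sample(orig, surr)
            row.update(ks_D=ks.D, ks_p=ks.p)
        else:
            row.update(ks_D=np.nan, ks_p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
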