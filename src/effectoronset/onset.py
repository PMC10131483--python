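"""Maternal/zygotic classification and expression-onset calling on FPKM time courses.

Whole-embryo RNA-seq samples the grid 0 hpf (fertilized egg) then 6-30 hpf at
2-hour intervals; replicate FPKM values are averaged before any calling. The
rules, applied to each gene's averaged trajectory:

* detected      — some grid value strictly exceeds ``expr_threshold`` (3 FPKM);
* maternal      — FPKM(0) > 3: the transcript was deposited in the egg, so a
                  zygotic onset cannot be read off directly;
* zygotic_clear — FPKM(0) < 1 and the trajectory first crosses 3 at >= 6 hpf;
                  onset is that first strict crossing;
* ambiguous_t0  — FPKM(0) in [1, 3]: neither clearly maternal nor clearly
                  absent at fertilization; onset left undefined.

For maternal genes a zygotic onset can still be *inferred* when the maternal
transcript visibly decays and embryonic transcription takes over: a minimum
inside the early window (6-10 hpf) below the 0-hpf level, followed by a rise
back above the expression threshold (the dip-then-rise rule).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sampling grid in hours post-fertilization.
TIME_GRID: tuple[int, ...] = (0, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30)

DEFAULT_EARLY_WINDOW: tuple[int, ...] = (6, 8, 10)

ORIGIN_CLASSES = ("maternal", "zygotic_clear", "ambiguous_t0", "undetected")


def _check_grid(columns) -> list[int]:
    hours = [int(c) for c in columns]
    if hours != sorted(hours) or len(set(hours)) != len(hours):
        raise ValueError(f"time grid must be strictly increasing, got {hours}")
    if 0 not in hours:
        raise ValueError("time grid must contain 0 hpf")
    return hours


def average_replicates(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of replicate genes x timepoints FPKM matrices.

    All replicates must share the same genes (same order) and the same grid.
    """
    if not replicates:
        raise ValueError("no replicates given")
    first = replicates[0]
    for i, rep in enumerate(replicates[1:], start=2):
        if not rep.index.equals(first.index):
            raise ValueError(f"replicate {i} gene set/order differs from replicate 1")
        if list(rep.columns) != list(first.columns):
            raise ValueError(f"replicate {i} time grid differs from replicate 1")
    avg = sum(r.astype(float) for r in replicates) / len(replicates)
    avg.attrs["replicate_averaged"] = True
    return avg


def call_onset(
    matrix: pd.DataFrame,
    expr_threshold: float = 3.0,
    maternal_threshold: float = 3.0,
    zygotic_t0_max: float = 1.0,
) -> pd.DataFrame:
    """Classify transcript origin and call first-crossing onsets per gene.

    ``matrix`` is genes x hours (columns are the hour grid, as ints or
    int-parseable labels) of replicate-averaged FPKM. Returns a frame indexed
    by gene with columns ``detected`` (bool), ``origin``, ``onset_hpf``
    (float, NaN when undefined) and ``method`` (``first_crossing`` /
    ``dip_rise`` / ``undefined``). Dip-rise onsets for maternal genes are
    added separately by :func:`annotate_dip_rise`.
    """
    if expr_threshold < 0 or maternal_threshold < 0 or zygotic_t0_max < 0:
        raise ValueError("thresholds must be >= 0")
    if zygotic_t0_max > expr_threshold:
        raise ValueError(
            f"zygotic_t0_max ({zygotic_t0_max}) must not exceed "
            f"expr_threshold ({expr_threshold})"
        )
    hours = _check_grid(matrix.columns)
    values = matrix.to_numpy(dtype=float)
    t0 = values[:, hours.index(0)]
    detected = (values > expr_threshold).any(axis=1)

    origin = np.full(values.shape[0], "undetected", dtype=object)
    onset = np.full(values.shape[0], np.nan)
    method = np.full(values.shape[0], "undefined", dtype=object)

    maternal = detected & (t0 > maternal_threshold)
    origin[maternal] = "maternal"

    hour_arr = np.asarray(hours, dtype=float)
    above = values > expr_threshold
    first_idx = np.where(above.any(axis=1), above.argmax(axis=1), -1)
    first_hour = np.where(first_idx >= 0, hour_arr[first_idx], np.nan)

    zygotic = detected & (t0 < zygotic_t0_max) & (first_hour >= 6)
    origin[zygotic] = "zygotic_clear"
    onset[zygotic] = first_hour[zygotic]
    method[zygotic] = "first_crossing"

    ambiguous = detected & ~maternal & ~zygotic
    origin[ambiguous] = "ambiguous_t0"

    out = pd.DataFrame(
        {"detected": detected, "origin": origin, "onset_hpf": onset, "method": method},
        index=matrix.index,
    )
    out.index.name = matrix.index.name or "gene_id"
    return out


def infer_dip_rise_onset(
    trajectory: Mapping[int, float] | pd.Series,
    early_window: Sequence[int] = DEFAULT_EARLY_WINDOW,
    expr_threshold: float = 3.0,
    maternal_threshold: float = 3.0,
) -> float | None:
    """Inferred zygotic onset of a maternal gene from a dip-then-rise pattern.

    Let ``t_min`` be the timepoint of the minimum FPKM inside the early window
    (ties to the earliest hour). The rule fires iff the minimum lies strictly
    below the 0-hpf level (the maternal transcript decayed) and some later
    timepoint rises strictly above both that minimum and ``expr_threshold``
    (embryonic transcription took over); the onset is the earliest such
    timepoint. Returns ``None`` when the pattern is absent.

    Raises
    ------
    ValueError
        If the trajectory is not maternal (FPKM at 0 hpf not above
        ``maternal_threshold``) — the rule is only defined for maternal genes.
    """
    series = pd.Series(dict(trajectory)) if not isinstance(trajectory, pd.Series) else trajectory
    series = series.copy()
    series.index = [int(h) for h in series.index]
    hours = _check_grid(series.index)

    t0_value = float(series.loc[0])
    if t0_value <= maternal_threshold:
        raise ValueError(
            "dip-rise inference is defined for maternal genes only "
            f"(FPKM(0) = {t0_value} is not > {maternal_threshold})"
        )
    window = [h for h in early_window if h in series.index]
    if not window:
        raise ValueError(f"no early-window hours {tuple(early_window)} on the grid {hours}")

    window_vals = series.loc[window]
    t_min = int(window_vals.idxmin())  # first occurrence -> earliest hour
    v_min = float(window_vals.min())
    if not v_min < t0_value:
        return None
    later = series.loc[[h for h in hours if h > t_min]]
    rising = later[(later > v_min) & (later > expr_threshold)]
    if rising.empty:
        return None
    return float(rising.index[0])


def annotate_dip_rise(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    early_window: Sequence[int] = DEFAULT_EARLY_WINDOW,
    expr_threshold: float = 3.0,
    maternal_threshold: float = 3.0,
) -> pd.DataFrame:
    """Add a ``dip_rise_onset_hpf`` column with inferred onsets for maternal genes.

    Genes keep their maternal origin; the inferred onset lives in its own
    column (NaN for everything non-maternal or without the pattern), and
    ``method`` becomes ``dip_rise`` where it fired.
    """
    out = calls.copy()
    out["dip_rise_onset_hpf"] = np.nan
    maternal_genes = out.index[out["origin"] == "maternal"]
    for g in maternal_genes:
        onset = infer_dip_rise_onset(
            matrix.loc[g],
            early_window=early_window,
            expr_threshold=expr_threshold,
            maternal_threshold=maternal_threshold,
        )
        if onset is not None:
            out.loc[g, "dip_rise_onset_hpf"] = onset
            out.loc[g, "method"] = "dip_rise"
    return out
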