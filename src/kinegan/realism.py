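"""Quantitative and qualitative comparison of real vs synthetic trials.

Range of motion (max - min per channel) is the quantitative realism
statistic: per (task, channel, group) cell, the ROM distributions of real
and synthetic trials are compared with a two-sided Welch t-test, producing
a 10 x 9 x 3 p-value grid. Spectral band power quantifies residual
high-frequency energy, and a t-SNE embedding of flattened trials gives the
qualitative picture (color = task, marker = group, fill = provenance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .channels import (
    CHANNEL_NAMES,
    GROUPS,
    N_CHANNELS,
    N_GROUPS,
    N_TASKS,
    SAMPLE_RATE_HZ,
    TASKS,
)
from .trials import Dataset, KinematicTrial


def range_of_motion(trial) -> np.ndarray:
    """Channel-wise max - min over the trial; nonnegative 9-vector."""
    signal = trial.signal if isinstance(trial, KinematicTrial) else np.asarray(trial, dtype=float)
    return signal.max(axis=0) - signal.min(axis=0)


def rom_matrix(dataset: Dataset) -> np.ndarray:
    """Per-trial ROM summaries stacked into an (N, 9) matrix."""
    return np.array([range_of_motion(t) for t in dataset])


def rom_ttest(real_roms: np.ndarray, synth_roms: np.ndarray) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value on two ROM samples.

    Degenerate case (zero variance on both sides): p = 1 when the means are
    equal, 0 otherwise. Requires at least 2 samples per side.
    """
    a = np.asarray(real_roms, dtype=float)
    b = np.asarray(synth_roms, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("rom_ttest needs at least 2 samples per side")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


@dataclass
class RomTable:
    """10 tasks x 9 channels x 3 groups grid of ROM-comparison p-values.

    Cells with fewer than 2 trials on either side hold NaN and are flagged
    in ``insufficient``. ``n_real`` / ``n_synth`` record per-cell sample
    sizes.
    """

    p_values: np.ndarray  # (10, 9, 3)
    n_real: np.ndarray  # (10, 3)
    n_synth: np.ndarray  # (10, 3)

    @property
    def insufficient(self) -> np.ndarray:
        return np.isnan(self.p_values)

    def significant_fraction(self, alpha: float = 0.05) -> float:
        """Fraction of computable cells with p < alpha (no multiplicity
        correction; the grid is reported raw)."""
        valid = ~self.insufficient
        if not valid.any():
            return float("nan")
        return float((self.p_values[valid] < alpha).mean())

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table: task rows, channel columns, one row per group."""
        rows = []
        for ti, task in enumerate(TASKS):
            for gi, group in enumerate(GROUPS):
                row = {"task": task, "group": group}
                row.update(
                    {ch: self.p_values[ti, ci, gi] for ci, ch in enumerate(CHANNEL_NAMES)}
                )
                rows.append(row)
        return pd.DataFrame(rows)


def rom_table(real: Dataset, synth: Dataset) -> RomTable:
    """Welch p-value per (task, channel, group) cell comparing real vs
    synthetic range of motion."""
    p = np.full((N_TASKS, N_CHANNELS, N_GROUPS), np.nan)
    n_real = np.zeros((N_TASKS, N_GROUPS), dtype=int)
    n_synth = np.zeros((N_TASKS, N_GROUPS), dtype=int)
    real_roms, real_tasks, real_groups = rom_matrix(real), real.task_labels, real.group_labels
    synth_roms, synth_tasks, synth_groups = rom_matrix(synth), synth.task_labels, synth.group_labels
    for ti in range(N_TASKS):
        for gi in range(N_GROUPS):
            ra = real_roms[(real_tasks == ti) & (real_groups == gi)]
            sa = synth_roms[(synth_tasks == ti) & (synth_groups == gi)]
            n_real[ti, gi], n_synth[ti, gi] = len(ra), len(sa)
            if len(ra) < 2 or len(sa) < 2:
                continue
            for ci in range(N_CHANNELS):
                p[ti, ci, gi] = rom_ttest(ra[:, ci], sa[:, ci])
    return RomTable(p, n_real, n_synth)


def highband_power_ratio(
    batch: np.ndarray, cutoff_hz: float = 2.0, fs: float = SAMPLE_RATE_HZ
) -> float:
    """Fraction of non-DC signal power above the cutoff frequency.

    Parseval-consistent one-sided periodogram (interior rfft bins doubled),
    averaged over samples and channels by pooling power. In [0, 1].
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim == 2:
        batch = batch[None]
    if batch.ndim != 3 or batch.shape[0] < 1:
        raise ValueError("expected a nonempty (B, L, C) or (L, C) batch")
    n = batch.shape[1]
    power = np.abs(np.fft.rfft(batch, axis=1)) ** 2
    # one-sided scaling: double every bin except DC and (for even n) Nyquist
    scale = np.full(power.shape[1], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = power * scale[None, :, None]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nondc = power[:, 1:, :]
    total = nondc.sum()
    if total == 0:
        return 0.0
    high = power[:, freqs > cutoff_hz, :].sum()
    return float(high / total)


def tsne_embed(
    real: Dataset,
    synth: Dataset,
    seed: int = 0,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """2-D t-SNE embedding of flattened, per-channel-standardized trials.

    Returns a frame with columns x, y, task, group, provenance (real rows
    first). Perplexity defaults to min(30, N/4) and the combined dataset
    must hold at least 3 * perplexity trials.
    """
    combined = real.extend(synth)
    x = combined.signals()
    n = x.shape[0]
    if perplexity is None:
        perplexity = min(30.0, n / 4.0)
    if n < 3 * perplexity or n < 6:
        raise ValueError(f"{n} trials is too few for perplexity {perplexity}")
    mean = x.mean(axis=(0, 1))
    sd = np.where(x.std(axis=(0, 1)) > 0, x.std(axis=(0, 1)), 1.0)
    flat = ((x - mean) / sd).reshape(n, -1)
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(flat)
    return pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "task": [t.task for t in combined],
            "group": [t.group for t in combined],
            "provenance": [t.provenance for t in combined],
        }
    )


def plot_tsne(embedding: pd.DataFrame, ax=None):
    """Scatter of a t-SNE embedding: color = task, marker = group,
    open markers = synthetic, filled = real."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    markers = {"control": "o", "mild": "^", "modsev": "s"}
    cmap = plt.get_cmap("tab10")
    task_color = {task: cmap(i) for i, task in enumerate(TASKS)}
    for (task, group, prov), sub in embedding.groupby(["task", "group", "provenance"]):
        color = task_color[task]
        ax.scatter(
            sub["x"],
            sub["y"],
            marker=markers[group],
            facecolors=color if prov == "real" else "none",
            edgecolors=color,
            s=25,
            linewidths=0.8,
        )
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    return ax
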