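"""Kernel-based network simulation and spontaneous-correlation prediction.

Given the atlas of trial-averaged propagation kernels, activity is simulated
without assuming network dynamical equations: driving one neuron with a
representative transient, every other neuron's response is the convolution of
the drive with the pair's kernel.  Per-drive correlation matrices are averaged
over a drive set (all neurons or a greedily selected "top-n" subset), and
agreement with an observed correlation matrix is the Pearson correlation of
their off-diagonal entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import Kernel, apply_kernel

Q_THRESHOLD = 0.05


@dataclass
class KernelAtlas:
    """Trial-averaged kernels per ordered pair, with q per pair.

    Pairs with q > 0.05 are considered not connected and carry the zero
    kernel when simulating.
    """

    n_neurons: int
    kernels: dict[tuple[int, int], Kernel] = field(default_factory=dict)
    q: dict[tuple[int, int], float] = field(default_factory=dict)

    def effective_kernel(self, j: int, i: int) -> Kernel:
        k = self.kernels.get((j, i))
        if k is None:
            return Kernel()
        if self.q.get((j, i), 0.0) > Q_THRESHOLD:
            return Kernel()
        return k


def predict_correlations(atlas: KernelAtlas, drive_set: list[int],
                         drive_waveform: np.ndarray, dt: float) -> np.ndarray:
    """Mean over drives of the per-drive activity correlation matrix.

    For each driven neuron j, neuron i's activity is ``k_ij * drive`` (the
    driven neuron's own activity is the drive waveform); constant activities
    correlate 0 with everything.  The returned matrix is symmetric with unit
    diagonal.
    """
    if not drive_set:
        raise ValueError("drive_set must contain at least one neuron")
    n = atlas.n_neurons
    acc = np.zeros((n, n))
    for j in drive_set:
        acts = np.zeros((len(drive_waveform), n))
        for i in range(n):
            if i == j:
                acts[:, i] = drive_waveform
            else:
                acts[:, i] = apply_kernel(atlas.effective_kernel(j, i),
                                          drive_waveform, dt)
        acc += _safe_corr(acts)
    out = acc / len(drive_set)
    np.fill_diagonal(out, 1.0)
    return out


def _safe_corr(acts: np.ndarray) -> np.ndarray:
    sd = acts.std(axis=0)
    ok = sd > 0
    n = acts.shape[1]
    c = np.zeros((n, n))
    if ok.sum() >= 2:
        c[np.ix_(ok, ok)] = np.corrcoef(acts[:, ok], rowvar=False)
    np.fill_diagonal(c, 1.0)
    return c


def corr_agreement(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation of off-diagonal upper-triangle entries."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.shape[0] != pred.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    iu = np.triu_indices_from(pred, k=1)
    a, b = pred[iu], obs[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant off-diagonal entries: agreement undefined")
    return float(np.corrcoef(a, b)[0, 1])


def select_top_n(atlas: KernelAtlas, target_corr: np.ndarray, n: int,
                 drive_waveform: np.ndarray, dt: float = 0.5) -> list[int]:
    """Greedy forward selection of the n drive neurons maximizing agreement.

    At each step the neuron whose addition to the drive set maximizes
    ``corr_agreement`` with the target matrix joins the set; ties break
    deterministically toward the lower neuron index.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > atlas.n_neurons:
        raise ValueError("n exceeds the number of neurons in the atlas")
    chosen: list[int] = []
    for _ in range(n):
        best_j, best_score = None, -np.inf
        for j in range(atlas.n_neurons):
            if j in chosen:
                continue
            try:
                score = corr_agreement(
                    predict_correlations(atlas, chosen + [j], drive_waveform, dt),
                    target_corr)
            except ValueError:
                score = -np.inf
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        if best_j is None:
            break
        chosen.append(best_j)
    return chosen
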