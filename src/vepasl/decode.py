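"""Maximum a posteriori separation of per-artery signals from VE data.

Each voxel's eight encoded measurements at one PLD follow a linear mixing
model S_e = static - sum_a (1 - w_ea) * dM_a, where w_ea is the encoding
matrix entry for cycle e and artery a.  Rather than inverting the full
mixing (which is poorly conditioned for arteries that do not feed the
voxel), the decoder entertains a small set of support classes — the empty
set, every single artery and every artery pair by default — solves the
restricted least-squares problem for each, and selects the class with the
highest posterior: Gaussian likelihood of the residuals times a class prior,
with a BIC-style complexity penalty so that nested classes do not trivially
win.  Class selection is shared across PLDs (log-posteriors summed), since a
voxel's set of feeding arteries does not depend on the readout delay.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, EncodingMatrix

logger = logging.getLogger(__name__)


def default_classes(n_arteries: int, max_size: int = 2) -> list[tuple[int, ...]]:
    """Artery-support classes: empty set, singletons and (by default) pairs.

    Supports of three or more major arteries in one voxel are physiologically
    rare and under-determined with eight encodings, so they are excluded
    unless ``max_size`` is raised.  Ordered by size so that ties in the
    posterior resolve to the smaller support.
    """
    classes: list[tuple[int, ...]] = []
    for size in range(0, max_size + 1):
        classes.extend(itertools.combinations(range(n_arteries), size))
    return classes


@dataclass
class VoxelDecodeResult:
    """Decoded per-artery signals for one voxel."""

    class_arteries: tuple[int, ...]
    dm: np.ndarray              # (n_arteries, n_plds) — zero outside the class
    static: np.ndarray          # (n_plds,)
    residual_variance: float
    log_posterior: float


def _class_design(matrix: EncodingMatrix, cls: tuple[int, ...]) -> np.ndarray:
    """Design matrix for one support class: -(1-w) columns plus a static column."""
    cols = [-(1.0 - matrix.weights[:, a]) for a in cls]
    cols.append(np.ones(matrix.n_encodings))
    return np.column_stack(cols)


def class_log_posterior(
    rss: np.ndarray,
    n_params: int,
    n_obs: int,
    noise_sd: float | np.ndarray,
    prior: float,
) -> np.ndarray:
    """Log posterior of a support class given its restricted-LS residual.

    Gaussian log-likelihood of the residuals at the supplied noise level,
    plus the log class prior, minus (k/2) log N per free parameter (the
    large-N Laplace/BIC approximation to the marginal likelihood) so that
    enlarging the support only pays off when it genuinely reduces residuals.
    """
    sigma2 = np.maximum(np.asarray(noise_sd, dtype=float) ** 2, 1e-300)
    return -rss / (2.0 * sigma2) - 0.5 * n_params * np.log(n_obs) + np.log(prior)


def decode_voxel(
    signals: np.ndarray,
    matrix: EncodingMatrix,
    classes: list[tuple[int, ...]] | None = None,
    prior: np.ndarray | None = None,
    noise_sd: float = 1.0,
) -> VoxelDecodeResult:
    """MAP decoding of one voxel.

    ``signals`` is (n_encodings,) for a single PLD or (n_plds, n_encodings)
    for joint class selection across PLDs.  Negative per-artery estimates are
    clipped to zero after solving.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))  # (P, E)
    n_plds, n_enc = signals.shape
    if n_enc != matrix.n_encodings:
        raise ValueError("signal length does not match number of encodings")
    if classes is None:
        classes = default_classes(matrix.n_arteries)
    if prior is None:
        prior = np.full(len(classes), 1.0 / len(classes))
    prior = np.asarray(prior, dtype=float)

    n_obs = signals.size
    best = None
    any_solved = False
    for cls, pr in zip(classes, prior):
        x = _class_design(matrix, cls)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            logger.info("skipping singular class %s", cls)
            continue
        any_solved = True
        beta, *_ = np.linalg.lstsq(x, signals.T, rcond=None)  # (k+1, P)
        resid = signals.T - x @ beta
        rss = float(np.sum(resid**2))
        lp = float(
            class_log_posterior(rss, x.shape[1] * n_plds, n_obs, noise_sd, pr)
        )
        if best is None or lp > best[0]:
            best = (lp, cls, beta, rss)
    if not any_solved:
        raise ValueError("all support classes are singular for this encoding matrix")

    lp, cls, beta, rss = best
    dm = np.zeros((matrix.n_arteries, n_plds))
    for i, a in enumerate(cls):
        dm[a] = np.clip(beta[i], 0.0, None)
    return VoxelDecodeResult(
        class_arteries=cls,
        dm=dm,
        static=beta[-1].copy(),
        residual_variance=rss / n_obs,
        log_posterior=lp,
    )


@dataclass
class DecodedSignals:
    """Per-artery difference signals for a whole series."""

    artery_ids: tuple[str, ...]
    classes: list[tuple[int, ...]]
    dm: np.ndarray              # (n_arteries, n_plds, nx, ny, nz)
    class_map: np.ndarray       # (nx, ny, nz) index into ``classes``
    static: np.ndarray          # (n_plds, nx, ny, nz)
    noise_sd: np.ndarray        # (nx, ny, nz) per-voxel noise SD (repeat-averaged)

    def territory_labels(self) -> np.ndarray:
        """Vascular-territory label map: 0 = no supply, a+1 = artery a for
        single-artery voxels, -1 for mixed-supply voxels."""
        labels = np.zeros(self.class_map.shape, dtype=int)
        for idx, cls in enumerate(self.classes):
            sel = self.class_map == idx
            if len(cls) == 1:
                labels[sel] = cls[0] + 1
            elif len(cls) > 1:
                labels[sel] = -1
        return labels


def _average_repeats(
    data: np.ndarray, sidecar_volumes: list[dict], n_plds: int, n_enc: int, n_rep: int
) -> tuple[np.ndarray, np.ndarray]:
    """Group volumes by (PLD, encoding) from the sidecar ordering.

    Returns the repeat-averaged data (P, E, N) and a per-voxel noise SD of
    the averaged volumes estimated from paired repetition differences.
    """
    shape = data.shape[:3]
    n_vox = int(np.prod(shape))
    flat = data.reshape(n_vox, data.shape[3])
    grouped = np.empty((n_plds, n_enc, n_rep, n_vox))
    seen = np.zeros((n_plds, n_enc, n_rep), dtype=bool)
    for vol in sidecar_volumes:
        p, e, r = vol["pld_index"], vol["cycle_index"], vol["repeat"]
        grouped[p, e, r] = flat[:, vol["index"]]
        seen[p, e, r] = True
    if not seen.all():
        raise ValueError("volume table does not cover every (PLD, encoding, repeat)")
    mean = grouped.mean(axis=2)
    if n_rep >= 2:
        # Var(v1 - v2) = 2 sigma^2 per volume; averaged volume: sigma^2 / n_rep
        diffs = grouped - mean[:, :, None]
        resid_var = (diffs**2).sum(axis=(0, 1, 2)) / (n_plds * n_enc * (n_rep - 1))
        noise_var = resid_var / n_rep
    else:
        noise_var = np.zeros(n_vox)
    return mean, np.sqrt(noise_var)


def decode_series(
    data: np.ndarray,
    protocol: AcquisitionProtocol,
    matrix: EncodingMatrix,
    sidecar_volumes: list[dict] | None = None,
    classes: list[tuple[int, ...]] | None = None,
    prior: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> DecodedSignals:
    """Decode every voxel of a 4D series with joint class selection over PLDs.

    Repetitions are averaged first; the noise SD is estimated per voxel from
    paired-repetition differences, floored at a global robust (median)
    estimate.  ``sidecar_volumes`` gives the acquisition order (defaults to
    the canonical schedule).
    """
    from .protocol import volume_schedule

    if data.shape[3] != protocol.n_volumes:
        raise ValueError(
            f"series has {data.shape[3]} volumes, protocol expects {protocol.n_volumes}"
        )
    if sidecar_volumes is None:
        sidecar_volumes = volume_schedule(protocol)
    if classes is None:
        classes = default_classes(matrix.n_arteries)
    if prior is None:
        prior = np.full(len(classes), 1.0 / len(classes))
    prior = np.asarray(prior, dtype=float)

    shape = data.shape[:3]
    n_plds, n_enc = protocol.n_plds, protocol.n_encodings
    y, noise_sd = _average_repeats(data, sidecar_volumes, n_plds, n_enc, protocol.n_repeats)
    n_vox = y.shape[2]

    if mask is not None:
        sel = mask.reshape(n_vox).astype(bool)
    else:
        sel = np.ones(n_vox, dtype=bool)
    ysel = y[:, :, sel]  # (P, E, M)

    # floor the per-voxel noise at a global robust level (and at a tiny
    # fraction of the signal scale, for noiseless input)
    floor = max(float(np.median(noise_sd[sel])), 1e-9 * float(np.abs(ysel).max() or 1.0))
    sigma = np.maximum(noise_sd[sel], floor)

    n_obs = n_plds * n_enc
    best_lp = np.full(ysel.shape[2], -np.inf)
    best_cls = np.zeros(ysel.shape[2], dtype=int)
    solutions = []
    for idx, (cls, pr) in enumerate(zip(classes, prior)):
        x = _class_design(matrix, cls)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            logger.info("skipping singular class %s", cls)
            solutions.append(None)
            continue
        pinv = np.linalg.pinv(x)
        beta = np.einsum("ke,pem->pkm", pinv, ysel)       # (P, k+1, M)
        resid = ysel - np.einsum("ek,pkm->pem", x, beta)
        rss = np.sum(resid**2, axis=(0, 1))               # (M,)
        lp = class_log_posterior(rss, x.shape[1] * n_plds, n_obs, sigma, pr)
        better = lp > best_lp
        best_lp[better] = lp[better]
        best_cls[better] = idx
        solutions.append(beta)
    if all(s is None for s in solutions):
        raise ValueError("all support classes are singular for this encoding matrix")

    dm_sel = np.zeros((matrix.n_arteries, n_plds, ysel.shape[2]))
    static_sel = np.zeros((n_plds, ysel.shape[2]))
    clipped = 0
    for idx, cls in enumerate(classes):
        beta = solutions[idx]
        if beta is None:
            continue
        voxels = best_cls == idx
        if not voxels.any():
            continue
        for i, a in enumerate(cls):
            vals = beta[:, i, voxels]
            clipped += int(np.sum(vals < -2 * sigma[voxels]))
            dm_sel[a, :, voxels] = np.clip(vals, 0.0, None).T
        static_sel[:, voxels] = beta[:, -1, voxels]
    if clipped:
        logger.info("clipped %d negative per-artery estimates beyond the noise level", clipped)

    dm = np.zeros((matrix.n_arteries, n_plds, n_vox))
    dm[:, :, sel] = dm_sel
    static = np.zeros((n_plds, n_vox))
    static[:, sel] = static_sel
    class_map = np.zeros(n_vox, dtype=int)
    class_map[sel] = best_cls

    return DecodedSignals(
        artery_ids=matrix.artery_ids,
        classes=list(classes),
        dm=dm.reshape(matrix.n_arteries, n_plds, *shape),
        class_map=class_map.reshape(shape),
        static=static.reshape(n_plds, *shape),
        noise_sd=noise_sd.reshape(shape),
    )
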