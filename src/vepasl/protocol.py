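"""Acquisition protocol, artery geometry and the vessel-encoding matrix.

A vessel-encoded pseudo-continuous ASL (VEPCASL) acquisition cycles through a
small set of labeling configurations ("encodings").  Non-selective cycles
label (or leave untouched) all arteries at once; selective cycles spatially
modulate the labeling efficiency across the labeling plane so that different
arteries receive different degrees of inversion.  The per-cycle, per-artery
labeling efficiencies form the encoding matrix that the decoder later inverts.

Conventions: an efficiency of -1 means fully labeled (inverted) blood, +1
means control (unlabeled); selective cycles fall in between depending on the
artery's position along the cycle's modulation direction.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

DEFAULT_CYCLE_NAMES = (
    "control",
    "label",
    "lr_0",
    "lr_1",
    "ap_0",
    "ap_1",
    "diag_0",
    "diag_1",
)

DEFAULT_ARTERY_IDS = ("RICA", "LICA", "RVA", "LVA")

#: Labeling-plane coordinates (right-left x, anterior-posterior y) in mm.
#: Plausible neck geometry for a phantom; override via ArteryGeometry/config.
DEFAULT_ARTERY_POSITIONS_MM = (
    (-30.0, 0.0),   # RICA
    (30.0, 0.0),    # LICA
    (-8.0, -20.0),  # RVA
    (8.0, -20.0),   # LVA
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and structure of a multi-PLD VEPCASL acquisition."""

    label_duration_s: float = 1.4
    nominal_plds_s: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
    tr_s: float = 4.1
    n_slices: int = 24
    readout_duration_ms: float = 1085.0
    n_repeats: int = 2
    encoding_cycle_names: tuple[str, ...] = DEFAULT_CYCLE_NAMES

    def __post_init__(self) -> None:
        if self.label_duration_s <= 0:
            raise ValueError("label duration must be positive")
        plds = np.asarray(self.nominal_plds_s, dtype=float)
        if plds.size == 0 or np.any(plds <= 0) or np.any(np.diff(plds) <= 0):
            raise ValueError("nominal PLDs must be positive and strictly increasing")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.readout_duration_ms <= 0:
            raise ValueError("readout duration must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def n_plds(self) -> int:
        return len(self.nominal_plds_s)

    @property
    def n_encodings(self) -> int:
        return len(self.encoding_cycle_names)

    @property
    def n_volumes(self) -> int:
        """Total volumes in the acquisition schedule."""
        return self.n_encodings * self.n_repeats * self.n_plds

    @property
    def slice_interval_s(self) -> float:
        return self.readout_duration_ms / 1000.0 / self.n_slices


def build_default_protocol() -> AcquisitionProtocol:
    """Protocol defaults for the 3 T multi-PLD VEPCASL study design.

    1.4 s labeling, six nominal PLDs 0.25-1.5 s, TR 4.1 s, 24 ascending
    slices read out in 1085 ms, 2 repeats of 8 encoding cycles per PLD
    (96 volumes in total).
    """
    return AcquisitionProtocol()


def effective_plds(protocol: AcquisitionProtocol, rounded: bool = True) -> list[float]:
    """Brain-average effective PLDs: nominal PLD + half the readout duration.

    With a 2D multi-slice readout, later slices are acquired at longer
    delays; averaged over slices the effective PLD sits half a readout after
    the nominal one.  ``rounded`` gives the 0.01 s reporting precision.
    """
    half = protocol.readout_duration_ms / 1000.0 / 2.0
    vals = [p + half for p in protocol.nominal_plds_s]
    if rounded:
        vals = [round(v, 2) for v in vals]
    return vals


def slice_pld(protocol: AcquisitionProtocol, pld_index: int, slice_index: int) -> float:
    """Post-labeling delay experienced by one slice of one nominal PLD.

    Slices are acquired in ascending order; slice k adds k slice intervals
    to the nominal PLD.
    """
    if not 0 <= pld_index < protocol.n_plds:
        raise IndexError(f"pld_index {pld_index} out of range")
    if not 0 <= slice_index < protocol.n_slices:
        raise IndexError(f"slice_index {slice_index} out of range")
    return protocol.nominal_plds_s[pld_index] + slice_index * protocol.slice_interval_s


def volume_schedule(protocol: AcquisitionProtocol) -> list[dict]:
    """Canonical ordering of acquired volumes.

    For each nominal PLD, each repeat cycles through all encodings.  The
    schedule is carried in the sidecar so the decoder can consume reordered
    series.
    """
    table = []
    idx = 0
    for p in range(protocol.n_plds):
        for r in range(protocol.n_repeats):
            for e in range(protocol.n_encodings):
                table.append(
                    {
                        "index": idx,
                        "pld_index": p,
                        "repeat": r,
                        "cycle_index": e,
                        "cycle": protocol.encoding_cycle_names[e],
                    }
                )
                idx += 1
    return table


@dataclass(frozen=True)
class ArteryGeometry:
    """Positions of the brain-feeding arteries in the labeling plane."""

    artery_ids: tuple[str, ...] = DEFAULT_ARTERY_IDS
    positions_mm: tuple[tuple[float, float], ...] = DEFAULT_ARTERY_POSITIONS_MM

    def __post_init__(self) -> None:
        if len(self.artery_ids) != len(self.positions_mm):
            raise ValueError("artery_ids and positions_mm length mismatch")
        if len(self.artery_ids) < 2:
            raise ValueError("need at least 2 arteries")
        pos = np.asarray(self.positions_mm, dtype=float)
        if len({tuple(p) for p in pos}) != len(pos):
            raise ValueError("artery positions must be pairwise distinct")

    @property
    def n_arteries(self) -> int:
        return len(self.artery_ids)

    def positions(self) -> np.ndarray:
        return np.asarray(self.positions_mm, dtype=float)


def default_cycle_scheme() -> list[dict]:
    """The 8-cycle scheme: non-selective label/control, two left-right,
    two anterior-posterior and two diagonal selective cycles.

    Each selective cycle names a unit modulation direction and the pair of
    target arteries placed at efficiencies -1 and +1.  The second cycle of a
    pair flips the phase (swaps the targets' signs).  The diagonal cycles'
    orientation is not uniquely determined by the study description, so it is
    part of this (overridable) scheme rather than hard-coded elsewhere.
    """
    s2 = 1.0 / np.sqrt(2.0)
    return [
        {"name": "control", "type": "control"},
        {"name": "label", "type": "label"},
        {"name": "lr_0", "type": "selective", "direction": (1.0, 0.0),
         "target_low": "RICA", "target_high": "LICA"},
        {"name": "lr_1", "type": "selective", "direction": (1.0, 0.0),
         "target_low": "LICA", "target_high": "RICA"},
        {"name": "ap_0", "type": "selective", "direction": (0.0, 1.0),
         "target_low": "RICA", "target_high": "RVA"},
        {"name": "ap_1", "type": "selective", "direction": (0.0, 1.0),
         "target_low": "RVA", "target_high": "RICA"},
        {"name": "diag_0", "type": "selective", "direction": (s2, s2),
         "target_low": "RICA", "target_high": "LVA"},
        {"name": "diag_1", "type": "selective", "direction": (s2, s2),
         "target_low": "LVA", "target_high": "RICA"},
    ]


@dataclass(frozen=True)
class EncodingMatrix:
    """Per-encoding, per-artery labeling efficiencies in [-1, +1]."""

    weights: np.ndarray  # (n_encodings, n_arteries)
    artery_ids: tuple[str, ...]
    cycle_descriptions: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[1] != len(self.artery_ids):
            raise ValueError("weights shape does not match artery_ids")
        if w.shape[0] != len(self.cycle_descriptions):
            raise ValueError("weights shape does not match cycle_descriptions")
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ValueError("encoding weights must lie in [-1, +1]")

    @property
    def n_encodings(self) -> int:
        return self.weights.shape[0]

    @property
    def n_arteries(self) -> int:
        return self.weights.shape[1]

    def augmented(self) -> np.ndarray:
        """Weights with a constant static-tissue column appended."""
        return np.column_stack([self.weights, np.ones(self.n_encodings)])

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["cycle", *self.artery_ids])
        for name, row in zip(self.cycle_descriptions, self.weights):
            writer.writerow([name, *[f"{v:.6f}" for v in row]])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "EncodingMatrix":
        rows = list(csv.reader(io.StringIO(text)))
        header = rows[0]
        artery_ids = tuple(header[1:])
        names = tuple(r[0] for r in rows[1:])
        weights = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(weights=weights, artery_ids=artery_ids, cycle_descriptions=names)


def _selective_weights(positions: np.ndarray, cycle: dict, artery_ids: tuple[str, ...]) -> np.ndarray:
    d = np.asarray(cycle["direction"], dtype=float)
    d = d / np.linalg.norm(d)
    proj = positions @ d
    ids = list(artery_ids)
    p_low = proj[ids.index(cycle["target_low"])]
    p_high = proj[ids.index(cycle["target_high"])]
    half_period = p_high - p_low
    if abs(half_period) < 1e-9:
        raise ValueError(
            f"cycle {cycle.get('name', '?')}: target arteries project to the "
            "same position along the modulation direction (ill-conditioned scheme)"
        )
    # Sinusoidal labeling-efficiency model: target_low sits at -1 (labeled),
    # target_high at +1 (control), everything else in between.
    w = -np.cos(np.pi * (proj - p_low) / half_period)
    return np.clip(w, -1.0, 1.0)


def build_encoding_matrix(
    geometry: ArteryGeometry,
    scheme: list[dict] | None = None,
    ideal: bool = False,
) -> EncodingMatrix:
    """Construct the encoding matrix for a geometry and cycle scheme.

    With ``ideal=True`` selective cycles take exact -1/0/+1 entries (targets
    at the extremes, every other artery unmodulated) — useful for tests and
    idealized simulations.  Otherwise the sinusoidal efficiency model places
    each artery on the modulation profile according to its projection.
    """
    if scheme is None:
        scheme = default_cycle_scheme()
    pos = geometry.positions()
    rows = []
    names = []
    for cycle in scheme:
        kind = cycle["type"]
        if kind == "control":
            rows.append(np.ones(geometry.n_arteries))
        elif kind == "label":
            rows.append(-np.ones(geometry.n_arteries))
        elif kind == "selective":
            if ideal:
                w = np.zeros(geometry.n_arteries)
                ids = list(geometry.artery_ids)
                w[ids.index(cycle["target_low"])] = -1.0
                w[ids.index(cycle["target_high"])] = 1.0
                rows.append(w)
            else:
                rows.append(_selective_weights(pos, cycle, geometry.artery_ids))
        else:
            raise ValueError(f"unknown cycle type {kind!r}")
        names.append(cycle.get("name", kind))
    matrix = EncodingMatrix(
        weights=np.array(rows),
        artery_ids=geometry.artery_ids,
        cycle_descriptions=tuple(names),
    )
    rank = np.linalg.matrix_rank(matrix.augmented(), tol=1e-8)
    if rank < geometry.n_arteries + 1:
        raise ValueError(
            "encoding scheme is ill-conditioned for this geometry "
            f"(augmented rank {rank} < {geometry.n_arteries + 1})"
        )
    return matrix
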