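"""Structural connectivity: reading, writing, synthesising and delay tables.

A :class:`Connectome` couples a weights matrix (connection strengths, row =
target node, column = source node) with a tract-lengths matrix (mm) and a
signal transmission speed (mm/ms).  Tract length divided by speed gives the
conduction delay of each connection, which the simulator discretises into an
integer number of integration steps (:func:`compute_delay_table`).

Connectomes travel as ZIP archives of plain ASCII matrices, one file per
field (``weights.txt``, ``tract_lengths.txt``, ``positions.txt``, ...), with
whitespace or comma delimiters.  Only the weights and tract-lengths files are
mandatory; everything else gets a documented default.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConnectomeFormatError, DimensionError

__all__ = [
    "Connectome",
    "DelayTable",
    "read_connectome_zip",
    "write_connectome_zip",
    "generate_synthetic_connectome",
    "compute_delay_table",
]

#: Default transmission speed in mm/ms (= m/s) for myelinated long-range fibres.
DEFAULT_SPEED = 4.0


@dataclass
class Connectome:
    """Weighted, delayed structural network between brain regions.

    ``weights[i, j]`` is the strength of the connection *into* region ``i``
    *from* region ``j``; neither matrix is required to be symmetric.
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    region_labels: list[str] | None = None
    centres: np.ndarray | None = None
    areas: np.ndarray | None = None
    average_orientations: np.ndarray | None = None
    speed: float | np.ndarray = DEFAULT_SPEED
    hemispheres: np.ndarray | None = None  # True = right
    info: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        w, t = self.weights, self.tract_lengths
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionError(f"weights matrix must be square, got {w.shape}")
        if t.shape != w.shape:
            raise DimensionError(
                f"tract_lengths shape {t.shape} does not match weights {w.shape}"
            )
        if np.any(w < 0):
            raise ValueError("negative connection weight")
        if np.any(t < 0):
            raise ValueError("negative tract length")
        n = w.shape[0]
        if self.region_labels is None:
            self.region_labels = [f"region_{k}" for k in range(n)]
        if len(self.region_labels) != n:
            raise DimensionError("region_labels length does not match matrix size")
        if self.centres is None:
            self.centres = _unit_sphere_points(n)
        self.centres = np.asarray(self.centres, dtype=float)
        if self.centres.shape != (n, 3):
            raise DimensionError(f"centres must be (n, 3), got {self.centres.shape}")
        if self.areas is None:
            self.areas = np.ones(n)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.average_orientations is None:
            self.average_orientations = np.tile([0.0, 0.0, 1.0], (n, 1))
        self.average_orientations = np.asarray(self.average_orientations, dtype=float)
        speed = np.asarray(self.speed, dtype=float)
        if np.any(speed <= 0):
            raise ValueError("transmission speed must be positive")
        if speed.ndim == 0:
            self.speed = float(speed)
        elif speed.shape == (n, n):
            self.speed = speed
        else:
            raise DimensionError("speed must be a scalar or an n x n matrix")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class DelayTable:
    """Conduction delays discretised to integration steps."""

    delays_ms: np.ndarray
    delay_steps: np.ndarray
    horizon: int = field(init=False)

    def __post_init__(self):
        self.delay_steps = np.asarray(self.delay_steps, dtype=np.int64)
        if np.any(self.delay_steps < 0):
            raise ValueError("delay steps must be non-negative")
        # one slot for the current state on top of the maximum delay
        self.horizon = int(self.delay_steps.max()) + 1


def compute_delay_table(connectome: Connectome, dt: float) -> DelayTable:
    """Convert tract lengths and speed into integer delay steps.

    Delays are rounded half-away-from-zero to the nearest whole step;
    sub-step delays therefore round to 0 (instantaneous), with no
    minimum-one-step floor.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    delays_ms = connectome.tract_lengths / connectome.speed
    steps = np.floor(delays_ms / dt + 0.5).astype(np.int64)
    np.fill_diagonal(steps, 0)
    return DelayTable(delays_ms=delays_ms, delay_steps=steps)


# ---------------------------------------------------------------------------
# ZIP import / export

_FILE_ALIASES = {
    "weights": ("weights.txt", "weigths.txt"),  # both spellings occur in the wild
    "tract_lengths": ("tract_lengths.txt",),
    "positions": ("positions.txt", "centres.txt"),
    "areas": ("areas.txt",),
    "average_orientations": ("average_orientations.txt",),
    "info": ("info.txt",),
    "hemispheres": ("hemispheres.txt",),
}


def _parse_matrix(text: str) -> np.ndarray:
    cleaned = text.replace(",", " ")
    try:
        return np.loadtxt(io.StringIO(cleaned), ndmin=2)
    except ValueError as exc:
        raise ConnectomeFormatError(f"could not parse numeric table: {exc}") from exc


def _find_member(names: dict[str, str], key: str) -> str | None:
    for alias in _FILE_ALIASES[key]:
        if alias in names:
            return names[alias]
    return None


def read_connectome_zip(path) -> Connectome:
    """Read a connectome from a ZIP archive of delimited ASCII files.

    Mandatory members: a weights file (``weights.txt`` or the historical
    ``weigths.txt`` spelling) and ``tract_lengths.txt``.  Optional members
    supply positions (optionally with a leading label column), areas,
    average orientations, hemisphere flags and free-text info.
    """
    with zipfile.ZipFile(path) as zf:
        by_base = {name.rsplit("/", 1)[-1].lower(): name for name in zf.namelist()}

        def read_text(member: str) -> str:
            return zf.read(member).decode("utf-8")

        w_member = _find_member(by_base, "weights")
        if w_member is None:
            raise ConnectomeFormatError(
                "archive is missing the mandatory weights file "
                "(weights.txt / weigths.txt)"
            )
        t_member = _find_member(by_base, "tract_lengths")
        if t_member is None:
            raise ConnectomeFormatError(
                "archive is missing the mandatory tract_lengths.txt file"
            )
        weights = _parse_matrix(read_text(w_member))
        tract_lengths = _parse_matrix(read_text(t_member))

        labels = None
        centres = None
        p_member = _find_member(by_base, "positions")
        if p_member is not None:
            labels, centres = _parse_positions(read_text(p_member))

        areas = None
        a_member = _find_member(by_base, "areas")
        if a_member is not None:
            areas = _parse_matrix(read_text(a_member)).ravel()

        orientations = None
        o_member = _find_member(by_base, "average_orientations")
        if o_member is not None:
            orientations = _parse_matrix(read_text(o_member))

        hemispheres = None
        h_member = _find_member(by_base, "hemispheres")
        if h_member is not None:
            hemispheres = _parse_matrix(read_text(h_member)).ravel().astype(bool)

        info = ""
        i_member = _find_member(by_base, "info")
        if i_member is not None:
            info = read_text(i_member)

    return Connectome(
        weights=weights,
        tract_lengths=tract_lengths,
        region_labels=labels,
        centres=centres,
        areas=areas,
        average_orientations=orientations,
        hemispheres=hemispheres,
        info=info,
    )


def _parse_positions(text: str) -> tuple[list[str] | None, np.ndarray]:
    """Positions file: ``x y z`` per row, optionally prefixed by a label."""
    rows = [ln.replace(",", " ").split() for ln in text.splitlines() if ln.strip()]
    labels: list[str] | None
    try:
        float(rows[0][0])
        labels = None
        centres = np.array([[float(v) for v in r[:3]] for r in rows])
    except ValueError:
        labels = [r[0] for r in rows]
        centres = np.array([[float(v) for v in r[1:4]] for r in rows])
    return labels, centres


def write_connectome_zip(connectome: Connectome, path) -> None:
    """Write a connectome to the ZIP-of-ASCII interchange format."""

    def fmt(arr: np.ndarray) -> str:
        buf = io.StringIO()
        np.savetxt(buf, np.atleast_2d(arr), fmt="%.17g")
        return buf.getvalue()

    pos_lines = [
        f"{lbl} {x:.17g} {y:.17g} {z:.17g}"
        for lbl, (x, y, z) in zip(connectome.region_labels, connectome.centres)
    ]
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.txt", fmt(connectome.weights))
        zf.writestr("tract_lengths.txt", fmt(connectome.tract_lengths))
        zf.writestr("positions.txt", "\n".join(pos_lines) + "\n")
        zf.writestr("areas.txt", fmt(connectome.areas))
        zf.writestr("average_orientations.txt", fmt(connectome.average_orientations))
        if connectome.hemispheres is not None:
            zf.writestr("hemispheres.txt", fmt(connectome.hemispheres.astype(int)))
        zf.writestr("info.txt", connectome.info or "synthetic connectome\n")


# ---------------------------------------------------------------------------
# Synthetic connectomes

def _unit_sphere_points(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (Fibonacci lattice)."""
    k = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (k + 0.5) / n
    theta = 2 * np.pi * k / golden
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_synthetic_connectome(
    n_regions: int = 74,
    weight_levels: int = 4,
    seed: int = 42,
    radius: float = 65.0,
    speed: float = DEFAULT_SPEED,
) -> Connectome:
    """Build a two-hemisphere toy connectome with integer weight levels.

    Emulates the structure of a demonstration dataset: an even number of
    cortical regions split half/half between hemispheres, connection weights
    quantified as integers in ``[0, weight_levels - 1]``, and symmetric
    tract lengths equal to the Euclidean distance between region centres
    placed on a sphere of the given radius (mm).  Deterministic for a given
    seed.
    """
    if n_regions < 2:
        raise ValueError("a connectome needs at least 2 regions")
    if weight_levels < 2:
        raise ValueError("weight_levels must be at least 2")
    rng = np.random.default_rng(seed)

    half = n_regions // 2
    pts = _unit_sphere_points(n_regions - half, radius)
    right = np.column_stack([np.abs(pts[:, 0]) + 1.0, pts[:, 1], pts[:, 2]])
    left = right[:half] * np.array([-1.0, 1.0, 1.0])
    centres = np.vstack([left, right])

    weights = rng.integers(0, weight_levels, size=(n_regions, n_regions)).astype(float)
    np.fill_diagonal(weights, 0.0)

    diff = centres[:, None, :] - centres[None, :, :]
    tract_lengths = np.sqrt((diff**2).sum(axis=-1))

    labels = [f"lh_region_{k}" for k in range(half)] + [
        f"rh_region_{k}" for k in range(n_regions - half)
    ]
    hemispheres = np.array([False] * half + [True] * (n_regions - half))
    areas = rng.uniform(100.0, 3000.0, size=n_regions)
    orientations = centres / np.linalg.norm(centres, axis=1, keepdims=True)

    return Connectome(
        weights=weights,
        tract_lengths=tract_lengths,
        region_labels=labels,
        centres=centres,
        areas=areas,
        average_orientations=orientations,
        speed=speed,
        hemispheres=hemispheres,
        info=f"synthetic two-hemisphere connectome, n={n_regions}, seed={seed}\n",
    )
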