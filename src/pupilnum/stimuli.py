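"""Constrained dot-array stimuli and trial-design construction.

Arrays of non-overlapping bright dots are placed inside a circular field
centred on fixation, with a minimum edge-to-edge gap between dots and an
exclusion disc around the fixation point.  Adapter arrays use a common dot
diameter chosen so their summed surface area hits a fixed luminance-matching
target; test arrays either share one diameter (experiment 1) or jitter
diameters around that value (experiment 2) while keeping the mean diameter.

Note on feasibility: some published parameter sets request more total dot
area than the field can geometrically contain (e.g. 181 deg^2 of dots inside
an 11-deg-diameter field, which only has ~95 deg^2).  ``sample_positions``
detects such cases and raises :class:`PackingInfeasibleError`;
:func:`feasible_field_diameter` computes a widened field in which the same
dot set can be placed at a comfortable packing density.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TEST_NUMEROSITIES: tuple[int, ...] = (10, 14, 20, 28, 40)
ADAPT_CONDITIONS: tuple[str, str] = ("high", "low")

DESIGN_COLUMNS = [
    "participant_id",
    "experiment",
    "session",
    "condition",
    "trial",
    "numerosity",
]


class InvalidParameterError(ValueError):
    """A stimulus parameter is outside its admissible range."""


class PackingInfeasibleError(RuntimeError):
    """The requested dot set cannot be placed under the given constraints."""


@dataclass(frozen=True)
class StimulusSpec:
    """Geometric and luminance-matching parameters of the stimulus set."""

    test_numerosities: tuple[int, ...] = TEST_NUMEROSITIES
    test_total_area: float = 80.4  # deg^2
    adapter_total_area: float = 181.0  # deg^2
    adapter_high_n: int = 160
    adapter_low_n: int = 10
    background_luminance: float = 129.0  # cd/m^2
    field_diameter: float = 11.0  # deg
    min_gap: float = 0.25  # deg, edge to edge
    fixation_radius: float = 0.4  # deg, exclusion disc around fixation
    jitter_fraction: float = 0.5  # experiment-2 diameter range as a fraction

    def __post_init__(self) -> None:
        positives = {
            "test_total_area": self.test_total_area,
            "adapter_total_area": self.adapter_total_area,
            "adapter_high_n": self.adapter_high_n,
            "adapter_low_n": self.adapter_low_n,
            "field_diameter": self.field_diameter,
            "min_gap": self.min_gap,
            "fixation_radius": self.fixation_radius,
        }
        for name, value in positives.items():
            if value <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {value}")
        if list(self.test_numerosities) != sorted(self.test_numerosities):
            raise InvalidParameterError("test_numerosities must be sorted ascending")
        if any(n < 1 for n in self.test_numerosities):
            raise InvalidParameterError("test numerosities must be >= 1")
        if not 0 <= self.jitter_fraction < 2:
            raise InvalidParameterError("jitter_fraction must be in [0, 2)")

    def replace(self, **changes) -> "StimulusSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DotArray:
    """One stimulus: dot centres (deg from fixation) and diameters (deg)."""

    centers: np.ndarray  # (n, 2)
    diameters: np.ndarray  # (n,)
    numerosity: int
    role: str  # 'adapter-high' | 'adapter-low' | 'test'
    experiment: int = 1

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        diameters = np.asarray(self.diameters, dtype=float).reshape(-1)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "diameters", diameters)
        if len(centers) != len(diameters) or len(centers) != self.numerosity:
            raise InvalidParameterError(
                "centers, diameters and numerosity must agree: "
                f"{len(centers)}, {len(diameters)}, {self.numerosity}"
            )
        if np.any(diameters <= 0):
            raise InvalidParameterError("dot diameters must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "centers": self.centers.tolist(),
                "diameters": self.diameters.tolist(),
                "numerosity": int(self.numerosity),
                "role": self.role,
                "experiment": int(self.experiment),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DotArray":
        d = json.loads(text)
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            diameters=np.asarray(d["diameters"], dtype=float),
            numerosity=int(d["numerosity"]),
            role=d["role"],
            experiment=int(d.get("experiment", 1)),
        )


def equal_area_diameter(n: int, total_area: float) -> float:
    """Common diameter d such that ``n * pi * (d/2)**2 == total_area``."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if total_area <= 0:
        raise InvalidParameterError(f"total_area must be > 0, got {total_area}")
    return 2.0 * math.sqrt(total_area / (n * math.pi))


def total_area(array: DotArray | Sequence[float] | np.ndarray) -> float:
    """Summed circle area (deg^2) of an array or of a bare diameter list."""
    diameters = array.diameters if isinstance(array, DotArray) else np.asarray(array, float)
    if diameters.size == 0:
        return 0.0
    return float(np.sum(np.pi * (diameters / 2.0) ** 2))


def check_geometry(
    array: DotArray,
    field_diameter: float = 11.0,
    min_gap: float = 0.25,
    fixation_radius: float = 0.4,
) -> None:
    """Assert all placement invariants; raise ``InvalidParameterError`` if violated."""
    r = array.diameters / 2.0
    dist = np.hypot(array.centers[:, 0], array.centers[:, 1])
    field_r = field_diameter / 2.0
    if np.any(dist + r > field_r + 1e-9):
        raise InvalidParameterError("dot extends beyond the stimulus field")
    if np.any(dist < fixation_radius + r - 1e-9):
        raise InvalidParameterError("dot overlaps the fixation exclusion zone")
    if array.numerosity > 1:
        delta = array.centers[:, None, :] - array.centers[None, :, :]
        cc = np.hypot(delta[..., 0], delta[..., 1])
        gap = cc - (r[:, None] + r[None, :])
        iu = np.triu_indices(array.numerosity, k=1)
        if np.any(gap[iu] < min_gap - 1e-9):
            raise InvalidParameterError("dots closer than the minimum gap")


def sample_positions(
    n: int,
    diameters: Sequence[float] | np.ndarray,
    field_diameter: float = 11.0,
    min_gap: float = 0.25,
    fixation_radius: float = 0.4,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 10_000,
    max_restarts: int = 100,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping dot centres inside the field.

    Centres are proposed uniformly in the per-dot admissible annulus
    (inside the field, outside the fixation disc), dot by dot; after
    ``max_tries`` failed proposals for one dot the whole array restarts,
    and after ``max_restarts`` restarts a
    :class:`PackingInfeasibleError` is raised.  The same seed always
    returns the same positions.
    """
    diameters = np.asarray(diameters, dtype=float).reshape(-1)
    if n < 1 or len(diameters) != n:
        raise InvalidParameterError("need n >= 1 matching diameters")
    if np.any(diameters <= 0):
        raise InvalidParameterError("diameters must be positive")
    field_r = field_diameter / 2.0
    radii = diameters / 2.0

    # Hard impossibilities, reported before burning the sampling budget.
    if np.any(field_r - radii < fixation_radius + radii):
        raise PackingInfeasibleError(
            "dot too large for the field: containment (center distance + radius "
            f"<= {field_r:g}) and the fixation exclusion disc (radius "
            f"{fixation_radius:g}) leave no admissible centre"
        )
    if total_area(diameters) > math.pi * field_r**2:
        raise PackingInfeasibleError(
            f"total dot area {total_area(diameters):.1f} deg^2 exceeds the field "
            f"area {math.pi * field_r ** 2:.1f} deg^2: non-overlapping dots cannot "
            "all lie within the field"
        )

    if rng is None:
        rng = np.random.default_rng(seed)

    min_cc = radii[:, None] + radii[None, :] + min_gap  # centre-to-centre minima
    for _ in range(max_restarts):
        placed = np.empty((n, 2))
        ok = True
        for i in range(n):
            r_lo = fixation_radius + radii[i]
            r_hi = field_r - radii[i]
            success = False
            for _try in range(max_tries):
                # uniform over the annulus r_lo..r_hi
                rho = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
                theta = rng.uniform(0.0, 2.0 * math.pi)
                x, y = rho * math.cos(theta), rho * math.sin(theta)
                if i > 0:
                    d = np.hypot(placed[:i, 0] - x, placed[:i, 1] - y)
                    if np.any(d < min_cc[i, :i]):
                        continue
                placed[i] = (x, y)
                success = True
                break
            if not success:
                ok = False
                break
        if ok:
            return placed
    raise PackingInfeasibleError(
        f"could not place {n} dots (min gap {min_gap:g} deg) in a "
        f"{field_diameter:g}-deg field after {max_restarts} restarts of "
        f"{max_tries} proposals; the pairwise-gap constraint is too tight"
    )


def feasible_field_diameter(
    diameters: Sequence[float] | np.ndarray,
    min_gap: float = 0.25,
    target_density: float = 0.45,
) -> float:
    """Smallest field diameter placing this dot set at ``target_density``.

    Density is measured as summed gap-padded dot area over field area;
    rejection sampling is comfortable below ~0.5.
    """
    diameters = np.asarray(diameters, dtype=float)
    padded = total_area(diameters + min_gap)
    field_r = math.sqrt(padded / (target_density * math.pi)) + diameters.max() / 2.0
    return 2.0 * field_r


def sample_test_diameters(
    n: int,
    experiment: int,
    spec: StimulusSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dot diameters for one test array.

    Experiment 1: all dots share the equal-area diameter for ``n``.
    Experiment 2: diameters are drawn uniformly over a ``jitter_fraction``
    range around that value, preserving the mean diameter.
    """
    d0 = equal_area_diameter(n, spec.test_total_area)
    if experiment == 1:
        return np.full(n, d0)
    if experiment == 2:
        half = spec.jitter_fraction / 2.0
        return rng.uniform(d0 * (1.0 - half), d0 * (1.0 + half), size=n)
    raise InvalidParameterError(f"experiment must be 1 or 2, got {experiment}")


def make_adapter(
    condition: str,
    spec: StimulusSpec = StimulusSpec(),
    seed: int | None = None,
    field_diameter: float | None = None,
) -> DotArray:
    """Build an adapter array (equal dots summing to the adapter area target).

    ``field_diameter`` overrides the configured field (the published adapter
    geometry does not fit its printed field; see module docstring).
    """
    if condition not in ADAPT_CONDITIONS:
        raise InvalidParameterError(f"condition must be one of {ADAPT_CONDITIONS}")
    n = spec.adapter_high_n if condition == "high" else spec.adapter_low_n
    d = equal_area_diameter(n, spec.adapter_total_area)
    diameters = np.full(n, d)
    centers = sample_positions(
        n,
        diameters,
        field_diameter=field_diameter if field_diameter is not None else spec.field_diameter,
        min_gap=spec.min_gap,
        fixation_radius=spec.fixation_radius,
        seed=seed,
    )
    return DotArray(centers, diameters, n, role=f"adapter-{condition}")


def make_test(
    n: int,
    experiment: int,
    spec: StimulusSpec = StimulusSpec(),
    seed: int | None = None,
    field_diameter: float | None = None,
) -> DotArray:
    """Build a test array for one numerosity of either experiment."""
    if n not in spec.test_numerosities:
        raise InvalidParameterError(
            f"numerosity {n} not in allowed set {spec.test_numerosities}"
        )
    rng = np.random.default_rng(seed)
    diameters = sample_test_diameters(n, experiment, spec, rng)
    centers = sample_positions(
        n,
        diameters,
        field_diameter=field_diameter if field_diameter is not None else spec.field_diameter,
        min_gap=spec.min_gap,
        fixation_radius=spec.fixation_radius,
        rng=rng,
    )
    return DotArray(centers, diameters, n, role="test", experiment=experiment)


def render(
    array: DotArray,
    pixels_per_degree: float,
    background_level: float = 0.5,
    dot_level: float = 1.0,
    field_diameter: float | None = None,
) -> np.ndarray:
    """Rasterize an array to a square luminance map (row 0 = top).

    A pixel belongs to a dot when its centre lies within the dot radius, so
    bright-pixel count / ppd^2 approximates the summed dot area.
    """
    if pixels_per_degree <= 0:
        raise InvalidParameterError("pixels_per_degree must be positive")
    if field_diameter is None:
        if array.numerosity:
            extent = np.max(
                np.hypot(array.centers[:, 0], array.centers[:, 1])
                + array.diameters / 2.0
            )
            field_diameter = 2.0 * float(extent)
        else:
            field_diameter = 11.0
    size = int(math.ceil(field_diameter * pixels_per_degree))
    img = np.full((size, size), float(background_level))
    half = field_diameter / 2.0
    px = (np.arange(size) + 0.5) / pixels_per_degree - half  # x, rightward
    py = half - (np.arange(size) + 0.5) / pixels_per_degree  # y, upward
    X, Y = np.meshgrid(px, py)
    for (cx, cy), d in zip(array.centers, array.diameters):
        img[(X - cx) ** 2 + (Y - cy) ** 2 <= (d / 2.0) ** 2] = float(dot_level)
    return img


def save_render_png(img: np.ndarray, path: str | Path) -> None:
    """Write a luminance map in [0, 1] as an 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(img, float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def build_design(
    participants: Iterable[str | int],
    reps_per_numerosity_per_session: int = 18,
    seed: int = 0,
    experiment: int = 1,
    spec: StimulusSpec = StimulusSpec(),
) -> pd.DataFrame:
    """Build the full trial design table for a list of participants.

    Each participant runs 4 sessions, two per adaptation condition (session
    order shuffled), each session holding ``reps`` repetitions of every test
    numerosity in shuffled order — 360 trials per participant at the default
    18 repetitions.
    """
    if reps_per_numerosity_per_session < 1:
        raise InvalidParameterError("reps_per_numerosity_per_session must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in participants:
        conditions = rng.permutation(["high", "high", "low", "low"])
        for session_idx, condition in enumerate(conditions, start=1):
            numerosities = np.repeat(
                spec.test_numerosities, reps_per_numerosity_per_session
            )
            numerosities = rng.permutation(numerosities)
            for trial_idx, numerosity in enumerate(numerosities, start=1):
                rows.append(
                    (pid, experiment, session_idx, condition, trial_idx, int(numerosity))
                )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
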