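"""Spatial coding from a bilateral pair of projection neurons.

Geometry and decoding for the hexagonal-lattice stimulation experiment:
a conspecific is presented at lattice positions around the receiver and
the left/right projection-neuron (PN) responses are used to read out its
angular position.

Coordinate convention
---------------------
The receiver sits at the origin. ``x`` points frontal (ahead of the
fly), ``y`` points to the receiver's *right*. Angles are measured with
``atan2(y, x)`` in degrees: 0° is directly frontal, positive angles are
on the receiver's right, negative on its left, wrapped to (−180°, 180°].

The decoder is the linear model

    x ~ (R − L) + (R + L),   y ~ (R − L) + (R + L)

i.e. both coordinates of the male position on the unit circle are
predicted from the difference and the sum of the right and left PN
responses; the predicted angle is ``atan2(ŷ, x̂)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HexLattice",
    "BilateralResponse",
    "AngularTuning",
    "DecoderModel",
    "DecodingResult",
    "build_hex_lattice",
    "bilateral_contrast",
    "angular_tuning",
    "sincos_regression",
    "fit_decoder",
    "decode",
    "cross_validate_decoder",
    "wrap_angle_deg",
    "angular_error_deg",
]

SQRT3 = float(np.sqrt(3.0))
MIDDLE_RING = SQRT3  # mm, the fixed ring for angular tuning curves


def wrap_angle_deg(a):
    """Wrap angles (deg) to (−180°, 180°]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def angular_error_deg(a, b):
    """Absolute circular difference of two angle sets, in [0°, 180°]."""
    d = np.abs(np.asarray(wrap_angle_deg(np.asarray(a) - np.asarray(b))))
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class HexLattice:
    """Stimulus positions on a hexagonal lattice around the receiver."""

    positions: np.ndarray  # (n, 2) mm, columns (x frontal, y rightward)
    spacing: float

    @property
    def distances(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    @property
    def angles_deg(self) -> np.ndarray:
        return wrap_angle_deg(
            np.degrees(np.arctan2(self.positions[:, 1], self.positions[:, 0]))
        )

    @property
    def unique_angles(self) -> np.ndarray:
        return np.unique(np.round(self.angles_deg, 6))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class BilateralResponse:
    """One trial's paired left/right normalized peak response."""

    fly_id: int
    trial: int
    pos_index: int
    left: float
    right: float

    def __post_init__(self):
        if not (np.isfinite(self.left) and np.isfinite(self.right)):
            raise ValueError("responses must be finite")

    @property
    def diff(self) -> float:
        return self.right - self.left

    @property
    def sum(self) -> float:
        return self.right + self.left


@dataclass(frozen=True)
class AngularTuning:
    """Mean left/right tuning at the 11 lattice angles on the middle ring.

    Six angles (±30°, ±90°, ±150°) are measured directly on the √3 mm
    ring; the five angles present only on the 1 mm and 2 mm rings
    (0°, ±60°, ±120°) are linearly interpolated in distance to √3 mm.
    """

    angles: np.ndarray  # degrees, sorted, length 11
    left_mean: np.ndarray
    right_mean: np.ndarray
    left_sem: np.ndarray
    right_sem: np.ndarray
    provenance: np.ndarray  # "direct" | "interpolated" per angle

    def __post_init__(self):
        if len(self.angles) != 11:
            raise ValueError("angular tuning is defined at exactly 11 angles")


@dataclass(frozen=True)
class DecoderModel:
    """Linear position decoder: x̂ = a_x·diff + b_x·sum + c_x (y likewise)."""

    coef_x: tuple[float, float, float]  # (a_x, b_x, c_x)
    coef_y: tuple[float, float, float]
    target: str = "circle"  # "circle": unit-circle (cosθ, sinθ); "position": mm

    def predict(self, diff, total):
        diff = np.asarray(diff, dtype=float)
        total = np.asarray(total, dtype=float)
        ax, bx, cx = self.coef_x
        ay, by, cy = self.coef_y
        return ax * diff + bx * total + cx, ay * diff + by * total + cy


@dataclass(frozen=True)
class DecodingResult:
    """Per-trial decoded positions and their errors."""

    pred_x: np.ndarray
    pred_y: np.ndarray
    pred_angle_deg: np.ndarray
    true_angle_deg: np.ndarray
    angular_error_deg: np.ndarray  # wrapped to [0°, 180°]
    position_error: np.ndarray  # Euclidean, units of the decoder target

    @property
    def median_angular_error(self) -> float:
        return float(np.median(self.angular_error_deg))

    @property
    def mean_angular_error(self) -> float:
        return float(np.mean(self.angular_error_deg))

    @property
    def median_position_error(self) -> float:
        return float(np.median(self.position_error))


def build_hex_lattice(spacing: float = 1.0, max_distance: float = 2.0) -> HexLattice:
    """All non-origin hexagonal-lattice points within ``max_distance``,
    excluding any position directly behind the receiver (angle 180°).

    With the default spacing of 1 mm and radius 2 mm this yields the 16
    stimulation positions on rings of radius {1, √3, 2} mm and 11 unique
    angles at 30° steps from −150° to +150°.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if max_distance < spacing:
        raise ValueError("max_distance must be at least the lattice spacing")
    # hexagonal Bravais lattice: i·(1,0) + j·(1/2, √3/2), scaled by spacing
    kmax = int(np.ceil(max_distance / spacing)) + 1
    pts = []
    for i in range(-kmax, kmax + 1):
        for j in range(-kmax, kmax + 1):
            x = spacing * (i + 0.5 * j)
            y = spacing * (SQRT3 / 2.0 * j)
            r = np.hypot(x, y)
            if r < 1e-9 or r > max_distance * (1 + 1e-9):
                continue
            pts.append((x, y))
    pts = np.array(sorted(pts, key=lambda p: (round(np.hypot(*p), 9), np.arctan2(p[1], p[0]))))
    ang = wrap_angle_deg(np.degrees(np.arctan2(pts[:, 1], pts[:, 0])))
    keep = np.abs(np.abs(ang) - 180.0) > 1e-6
    return HexLattice(positions=pts[keep], spacing=spacing)


def bilateral_contrast(mean_ipsi: float, mean_contra: float) -> float:
    """Signed bilateral contrast: mean ipsilateral − mean contralateral
    response. Positive when the ipsilateral presentation drives the
    stronger response."""
    return float(mean_ipsi) - float(mean_contra)


def _mean_by_position(responses, lattice: HexLattice):
    """Per-position per-fly means, then across-fly mean and SEM."""
    n = len(lattice)
    fly_means_l: list[dict] = [dict() for _ in range(n)]
    fly_means_r: list[dict] = [dict() for _ in range(n)]
    for r in responses:
        fly_means_l[r.pos_index].setdefault(r.fly_id, []).append(r.left)
        fly_means_r[r.pos_index].setdefault(r.fly_id, []).append(r.right)
    mean_l = np.empty(n)
    mean_r = np.empty(n)
    sem_l = np.empty(n)
    sem_r = np.empty(n)
    for p in range(n):
        if not fly_means_l[p]:
            raise ValueError(f"no responses for lattice position {p}")
        ml = np.array([np.mean(v) for v in fly_means_l[p].values()])
        mr = np.array([np.mean(v) for v in fly_means_r[p].values()])
        mean_l[p], mean_r[p] = ml.mean(), mr.mean()
        sem_l[p] = ml.std(ddof=1) / np.sqrt(len(ml)) if len(ml) > 1 else 0.0
        sem_r[p] = mr.std(ddof=1) / np.sqrt(len(mr)) if len(mr) > 1 else 0.0
    return mean_l, mean_r, sem_l, sem_r


def angular_tuning(responses, lattice: HexLattice) -> AngularTuning:
    """Left/right mean tuning at the 11 angles of the √3 mm middle ring.

    Direct angles come from the √3 mm ring; the remaining five angles are
    linearly interpolated in distance between the 1 mm and 2 mm rings:
    ``v = v₁ₘₘ·(2 − √3) + v₂ₘₘ·(√3 − 1)``.
    """
    mean_l, mean_r, sem_l, sem_r = _mean_by_position(responses, lattice)
    d = lattice.distances
    a = np.round(lattice.angles_deg, 6)

    def ring(dist):
        return np.nonzero(np.abs(d - dist) < 1e-6)[0]

    w1 = 2.0 - SQRT3  # weight on the 1 mm value
    w2 = SQRT3 - 1.0  # weight on the 2 mm value
    rows = []
    for idx in ring(MIDDLE_RING):
        rows.append((a[idx], mean_l[idx], mean_r[idx], sem_l[idx], sem_r[idx], "direct"))
    inner, outer = ring(1.0 * lattice.spacing), ring(2.0 * lattice.spacing)
    for i_in in inner:
        match = [i_out for i_out in outer if abs(a[i_out] - a[i_in]) < 1e-6]
        if not match:
            raise ValueError(f"no 2 mm partner for inner-ring angle {a[i_in]}")
        i_out = match[0]
        rows.append((
            a[i_in],
            w1 * mean_l[i_in] + w2 * mean_l[i_out],
            w1 * mean_r[i_in] + w2 * mean_r[i_out],
            w1 * sem_l[i_in] + w2 * sem_l[i_out],
            w1 * sem_r[i_in] + w2 * sem_r[i_out],
            "interpolated",
        ))
    rows.sort(key=lambda r: r[0])
    ang, ml, mr, sl, sr, prov = map(np.array, zip(*rows))
    return AngularTuning(
        angles=ang.astype(float),
        left_mean=ml.astype(float),
        right_mean=mr.astype(float),
        left_sem=sl.astype(float),
        right_sem=sr.astype(float),
        provenance=prov,
    )


def _ols_1d(x: np.ndarray, y: np.ndarray):
    """Slope, intercept and R² of y ~ x by ordinary least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero variance in the predictor")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def sincos_regression(angles_deg, diff, total):
    """Regress the bilateral difference on sin(θ) and the sum on cos(θ).

    Returns a dict with ``(slope, intercept, r_squared)`` for each of the
    two regressions. Works on mean tuning curves or single trials.
    """
    th = np.radians(np.asarray(angles_deg, dtype=float))
    return {
        "diff_vs_sin": _ols_1d(np.sin(th), np.asarray(diff, dtype=float)),
        "sum_vs_cos": _ols_1d(np.cos(th), np.asarray(total, dtype=float)),
    }


def _design(responses):
    d = np.array([r.diff for r in responses])
    s = np.array([r.sum for r in responses])
    return np.column_stack([d, s, np.ones_like(d)])


def _targets(responses, lattice: HexLattice, target: str):
    ang = np.radians(lattice.angles_deg)
    pos = np.array([r.pos_index for r in responses])
    if target == "circle":
        return np.cos(ang)[pos], np.sin(ang)[pos]
    if target == "position":
        return lattice.positions[pos, 0], lattice.positions[pos, 1]
    raise ValueError(f"unknown decoder target {target!r}")


def fit_decoder(responses, lattice: HexLattice, target: str = "circle") -> DecoderModel:
    """Fit the bivariate linear decoder on single trials.

    ``target='circle'`` (default) predicts the male position on the unit
    circle, (cos θ, sin θ); ``target='position'`` predicts the raw (x, y)
    lattice coordinates in mm.
    """
    pos_ids = {r.pos_index for r in responses}
    if len(pos_ids) < 3:
        raise ValueError("need at least three distinct training positions")
    X = _design(responses)
    tx, ty = _targets(responses, lattice, target)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: diff and sum are collinear")
    cx, *_ = np.linalg.lstsq(X, tx, rcond=None)
    cy, *_ = np.linalg.lstsq(X, ty, rcond=None)
    return DecoderModel(coef_x=tuple(map(float, cx)), coef_y=tuple(map(float, cy)), target=target)


def decode(model: DecoderModel, responses, lattice: HexLattice) -> DecodingResult:
    """Decode single trials and score against the true lattice positions.

    The predicted angle is ``atan2(ŷ, x̂)``; angular errors are wrapped to
    [0°, 180°]; the position error is the Euclidean distance between the
    predicted point and the true target point.
    """
    d = np.array([r.diff for r in responses])
    s = np.array([r.sum for r in responses])
    px, py = model.predict(d, s)
    tx, ty = _targets(responses, lattice, model.target)
    pred_angle = wrap_angle_deg(np.degrees(np.arctan2(py, px)))
    true_angle = wrap_angle_deg(np.degrees(np.arctan2(ty, tx)))
    return DecodingResult(
        pred_x=px,
        pred_y=py,
        pred_angle_deg=np.atleast_1d(pred_angle),
        true_angle_deg=np.atleast_1d(true_angle),
        angular_error_deg=np.atleast_1d(angular_error_deg(pred_angle, true_angle)),
        position_error=np.hypot(px - tx, py - ty),
    )


def cross_validate_decoder(
    responses,
    lattice: HexLattice,
    scheme: str = "loo-fly",
    target: str = "circle",
) -> DecodingResult:
    """Decoder evaluation under three schemes.

    ``'loo-fly'`` (default) refits leaving each fly out in turn;
    ``'loo-trial'`` leaves out one (fly, trial, position) record at a
    time; ``'in-sample'`` trains and evaluates on the same data.
    """
    responses = list(responses)
    if scheme == "in-sample":
        model = fit_decoder(responses, lattice, target=target)
        return decode(model, responses, lattice)

    if scheme == "loo-fly":
        keys = sorted({r.fly_id for r in responses})
        group = lambda r: r.fly_id  # noqa: E731
    elif scheme == "loo-trial":
        keys = sorted({(r.fly_id, r.trial, r.pos_index) for r in responses})
        group = lambda r: (r.fly_id, r.trial, r.pos_index)  # noqa: E731
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    parts = []
    for k in keys:
        train = [r for r in responses if group(r) != k]
        test = [r for r in responses if group(r) == k]
        model = fit_decoder(train, lattice, target=target)
        parts.append(decode(model, test, lattice))
    return DecodingResult(
        pred_x=np.concatenate([p.pred_x for p in parts]),
        pred_y=np.concatenate([p.pred_y for p in parts]),
        pred_angle_deg=np.concatenate([p.pred_angle_deg for p in parts]),
        true_angle_deg=np.concatenate([p.true_angle_deg for p in parts]),
        angular_error_deg=np.concatenate([p.angular_error_deg for p in parts]),
        position_error=np.concatenate([p.position_error for p in parts]),
    )
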