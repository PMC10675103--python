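"""Trapezoidal fuzzy partitions.

Input universes (irrigation level in % ETc, sampling time in DAT) are
partitioned with equally spaced trapezoids whose breakpoints sit on the
grid ``x_j = xmin + j*k`` with delimiter spacing

    k = (xmax - xmin) / (2*n - 1)

so that adjacent ramps are complementary and the partition sums to one
everywhere on the universe.  Output universes (the biometric responses)
are partitioned into ten sets anchored on twenty empirical percentile
levels ``0, k, 2k, ..., 19k`` with ``k = 100/19`` (~5.26 % of the data
per level step); the outermost feet are extended by one segment width so
the extreme sets have full support below the minimum and above the
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DegenerateDataError

#: number of percentile levels delimiting the ten output sets
N_OUTPUT_SETS = 10
OUTPUT_LEVELS = tuple(j * (100.0 / 19.0) for j in range(20))


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoidal membership function with ordered breakpoints a<=b<=c<=d.

    Membership is 0 outside [a, d], 1 on the plateau [b, c], and linear on
    the ramps.  Degenerate ramps (a == b or c == d) behave as steps whose
    shared point has membership 1.
    """

    a: float
    b: float
    c: float
    d: float
    label: str = ""

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigError(
                f"trapezoid breakpoints must be ordered, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def membership(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        plateau = (x >= self.b) & (x <= self.c)
        out[plateau] = 1.0
        if self.b > self.a:
            rising = (x >= self.a) & (x < self.b)
            out[rising] = (x[rising] - self.a) / (self.b - self.a)
        if self.d > self.c:
            falling = (x > self.c) & (x <= self.d)
            out[falling] = (self.d - x[falling]) / (self.d - self.c)
        return out if out.ndim else float(out)

    def centroid(self) -> float:
        """Analytic centroid of the trapezoid, ∫x·μ(x)dx / ∫μ(x)dx."""
        a, b, c, d = self.a, self.b, self.c, self.d
        area = 0.5 * (b - a) + (c - b) + 0.5 * (d - c)
        if area == 0.0:
            return 0.5 * (a + d)
        moment = ((b - a) * (a + 2 * b) / 6.0
                  + 0.5 * (c * c - b * b)
                  + (d - c) * (2 * c + d) / 6.0)
        return moment / area

    def to_dict(self) -> dict:
        return {"label": self.label,
                "breakpoints": [self.a, self.b, self.c, self.d]}


@dataclass(frozen=True)
class FuzzyPartition:
    """Ordered family of trapezoids covering one universe."""

    universe: tuple[float, float]
    sets: tuple[TrapezoidMF, ...]
    anchors: tuple[float, ...]
    spacing_k: float

    def __post_init__(self):
        if len(self.anchors) != len(self.sets):
            raise ConfigError("one anchor required per fuzzy set")
        for anchor, mf in zip(self.anchors, self.sets):
            if mf.membership(anchor) != 1.0:
                raise ConfigError(
                    f"anchor {anchor} has membership < 1 in set {mf.label}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(mf.label for mf in self.sets)

    def memberships(self, x) -> np.ndarray:
        """Membership of each point in each set, shape ``(len(x), n_sets)``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.column_stack([mf.membership(x) for mf in self.sets])

    def to_dict(self) -> dict:
        return {
            "universe": list(self.universe),
            "spacing_k": self.spacing_k,
            "anchors": list(self.anchors),
            "sets": [mf.to_dict() for mf in self.sets],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FuzzyPartition":
        sets = tuple(
            TrapezoidMF(*entry["breakpoints"], label=entry["label"])
            for entry in payload["sets"]
        )
        return cls(universe=tuple(payload["universe"]), sets=sets,
                   anchors=tuple(payload["anchors"]),
                   spacing_k=payload["spacing_k"])


@dataclass(frozen=True)
class OutputPartitionSpec:
    """Percentile scaffolding behind an output partition."""

    percentile_levels: tuple[float, ...]
    delimiters: tuple[float, ...]
    extension: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "percentile_levels": list(self.percentile_levels),
            "delimiters": list(self.delimiters),
            "extension": list(self.extension),
        }


def compute_spacing(xmin: float, xmax: float, n_sets: int) -> float:
    """Delimiter spacing k = (xmax - xmin) / (2*n_sets - 1)."""
    if n_sets < 2:
        raise ConfigError("n_sets must be >= 2")
    if xmax <= xmin:
        raise ConfigError("xmax must exceed xmin")
    return (xmax - xmin) / (2 * n_sets - 1)


def build_input_partition(xmin: float, xmax: float, n_sets: int,
                          anchors, label_prefix: str = "S") -> FuzzyPartition:
    """Equally spaced trapezoid partition of an input universe.

    Breakpoints lie on ``x_j = xmin + j*k`` for j = -1 .. 2*n_sets; set i
    (1-based) is ``trapezoid(x_{2i-3}, x_{2i-2}, x_{2i-1}, x_{2i})``, so
    the first foot extends k below xmin and the last k above xmax.  Each
    supplied anchor must reach membership 1 in its own set.
    """
    k = compute_spacing(xmin, xmax, n_sets)
    anchors = tuple(float(a) for a in anchors)
    if len(anchors) != n_sets:
        raise ConfigError(f"expected {n_sets} anchors, got {len(anchors)}")

    def grid(j: int) -> float:
        return xmin + j * k

    sets = tuple(
        TrapezoidMF(grid(2 * i - 3), grid(2 * i - 2),
                    grid(2 * i - 1), grid(2 * i),
                    label=f"{label_prefix}{i}")
        for i in range(1, n_sets + 1)
    )
    for anchor, mf in zip(anchors, sets):
        if not (mf.b <= anchor <= mf.c):
            raise ConfigError(
                f"anchor {anchor} does not lie on the plateau of {mf.label}"
            )
    return FuzzyPartition(universe=(xmin, xmax), sets=sets,
                          anchors=anchors, spacing_k=k)


def irrigation_partition() -> FuzzyPartition:
    """Five sets L1..L5 over irrigation level 25..125 % ETc (k = 11.11 %)."""
    return build_input_partition(25.0, 125.0, 5,
                                 anchors=(25, 50, 75, 100, 125),
                                 label_prefix="L")


def dat_partition() -> FuzzyPartition:
    """Four sets P1..P4 over sampling time 14..35 DAT (k = 3 days)."""
    return build_input_partition(14.0, 35.0, 4,
                                 anchors=(14, 21, 28, 35),
                                 label_prefix="P")


def build_output_partition(
    values, n_sets: int = N_OUTPUT_SETS
) -> tuple[OutputPartitionSpec, FuzzyPartition]:
    """Percentile-anchored ten-set partition of an output universe.

    Empirical percentiles (linear interpolation between order statistics)
    are taken at the twenty levels ``j*100/19``; set m (1-based) is the
    trapezoid over delimiters ``2m-3 .. 2m`` on that level grid.  The
    first set's lower foot is extended below the minimum by P(k)-P(0) and
    the last set's upper foot above the maximum by P(100)-P(100-k).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n_levels = 2 * n_sets
    if values.size < n_levels:
        raise DegenerateDataError(
            f"need at least {n_levels} finite values, got {values.size}"
        )
    if np.ptp(values) == 0.0:
        raise DegenerateDataError(
            "all values equal; output partition is degenerate"
        )
    k = compute_spacing(0.0, 100.0, n_sets)
    levels = tuple(j * k for j in range(n_levels))
    delimiters = np.percentile(values, levels, method="linear")

    lower_ext = delimiters[1] - delimiters[0]
    upper_ext = delimiters[-1] - delimiters[-2]
    spec = OutputPartitionSpec(
        percentile_levels=levels,
        delimiters=tuple(float(v) for v in delimiters),
        extension=(float(lower_ext), float(upper_ext)),
    )

    def delim(j: int) -> float:
        if j < 0:
            return float(delimiters[0] - lower_ext)
        if j >= n_levels:
            return float(delimiters[-1] + upper_ext)
        return float(delimiters[j])

    sets = tuple(
        TrapezoidMF(delim(2 * m - 3), delim(2 * m - 2),
                    delim(2 * m - 1), delim(2 * m),
                    label=f"C{m}")
        for m in range(1, n_sets + 1)
    )
    anchors = tuple(0.5 * (mf.b + mf.c) for mf in sets)
    partition = FuzzyPartition(
        universe=(float(delimiters[0]), float(delimiters[-1])),
        sets=sets, anchors=anchors, spacing_k=k,
    )
    return spec, partition
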