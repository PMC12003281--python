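"""Closed-form model arithmetic: GhostConv savings ratios and the cosine
annealing learning-rate schedule.

GhostConv generates a fraction of its output feature maps with cheap
linear transforms instead of full convolutions.  For input channels ``c``,
primary kernel size ``k``, linear-transform kernel size ``d`` and ``s``
transformations, the compute ratio of standard convolution to GhostConv is

    r_s = (c·k²) / (c·k²/s + ((s−1)/s)·d²)

and the parameter ratio

    r_c = (n·c·k²) / ((n/s)·c·k² + (s−1)·(n/s)·d²),

both tending to ``s`` as ``c`` grows with ``d ≈ k``.  The spatial
dimensions (h, w, H, W) and kernel count ``n`` cancel from the exact forms;
they are carried in the spec for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["GhostConvSpec", "GhostRatios", "ScheduleSpec", "ghost_ratios", "cosine_lr"]


@dataclass(frozen=True)
class GhostConvSpec:
    """Dimensions of a GhostConv layer.

    ``s`` must divide ``n`` for the exact parameter-count form to hold.
    """

    c: int  # input channels
    k: int  # primary kernel size
    d: int  # linear-transform kernel size
    s: int  # number of transformations (1 = plain convolution)
    n: int = 2  # output kernels
    h: int = 1
    w: int = 1
    H: int = 1
    W: int = 1

    def __post_init__(self):
        for name in ("c", "k", "d", "s", "n", "h", "w", "H", "W"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n % self.s != 0:
            raise ValueError("s must divide n for the exact ratio form")


@dataclass(frozen=True)
class GhostRatios:
    """Exact compute (rs) and parameter (rc) savings ratios plus the
    asymptotic value s they approach for large channel counts."""

    rs: float
    rc: float
    asymptote: int


def ghost_ratios(spec: GhostConvSpec) -> GhostRatios:
    """Savings ratios of standard convolution over GhostConv.

    With ``s = 1`` both ratios are exactly 1 (no ghost features); both
    approach ``s`` as ``c → ∞`` with ``d ≈ k``.
    """
    c, k, d, s, n = spec.c, spec.k, spec.d, spec.s, spec.n
    rs = (c * k * k) / (c * k * k / s + (s - 1) / s * d * d)
    rc = (n * c * k * k) / ((n / s) * c * k * k + (s - 1) * (n / s) * d * d)
    return GhostRatios(rs=rs, rc=rc, asymptote=s)


@dataclass(frozen=True)
class ScheduleSpec:
    """Cosine-annealing schedule: decay from eta_max to eta_min over T_max
    training rounds along a half cosine."""

    eta_max: float = 0.007  # the study's initial SGD learning rate
    eta_min: float = 0.0
    t_max: int = 300

    def __post_init__(self):
        if self.eta_min > self.eta_max:
            raise ValueError("eta_min must not exceed eta_max")
        if self.t_max < 1:
            raise ValueError("t_max must be at least 1")


def cosine_lr(t: int, spec: ScheduleSpec) -> float:
    """Learning rate at round ``t`` (0-based, evaluated per epoch):

        η_t = η_min + ½ (η_max − η_min) (1 + cos(π t / T_max)).

    Non-increasing on [0, T_max]; η_0 = η_max, η_{T_max} = η_min.
    """
    if not (0 <= t <= spec.t_max):
        raise ValueError(f"t must be in [0, {spec.t_max}], got {t}")
    return spec.eta_min + 0.5 * (spec.eta_max - spec.eta_min) * (
        1.0 + math.cos(math.pi * t / spec.t_max)
    )
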