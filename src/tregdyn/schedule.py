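"""Piecewise-constant antigen-stimulation schedules beta(t)."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StimulationSchedule"]


@dataclass(frozen=True)
class StimulationSchedule:
    """Ordered, contiguous, non-overlapping segments of constant beta.

    Each segment is ``(t_start, t_end, beta)`` with ``beta >= 0``. Smoothly
    varying stimulation is intentionally unsupported: stimulation changes
    (antigen arrival, clearance) are modelled as switches.
    """

    segments: tuple[tuple[float, float, float], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        segs = tuple(
            (float(t0), float(t1), float(b)) for (t0, t1, b) in self.segments
        )
        if not segs:
            raise ValueError("schedule needs at least one segment")
        for t0, t1, b in segs:
            if not t1 > t0:
                raise ValueError(f"segment ({t0}, {t1}) has non-positive length")
            if b < 0:
                raise ValueError(f"beta must be >= 0, got {b}")
        for (_, t1, _), (t0n, _, _) in zip(segs, segs[1:]):
            if abs(t1 - t0n) > 1e-12 * max(1.0, abs(t1)):
                raise ValueError(
                    f"segments must be contiguous: gap/overlap at t={t1} vs {t0n}"
                )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, beta: float, t_end: float, t_start: float = 0.0):
        return cls(((t_start, t_end, beta),))

    @classmethod
    def from_string(cls, text: str) -> "StimulationSchedule":
        """Parse ``"0:100:0.5,100:2000:0"`` into a schedule."""
        segs = []
        for chunk in text.split(","):
            parts = chunk.split(":")
            if len(parts) != 3:
                raise ValueError(f"bad schedule segment {chunk!r}")
            segs.append(tuple(float(x) for x in parts))
        return cls(tuple(segs))

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def covers(self, t0: float, t1: float) -> bool:
        return self.t_start <= t0 and self.t_end >= t1

    def beta_at(self, t: float) -> float:
        for t0, t1, b in self.segments:
            if t0 <= t < t1:
                return b
        if t == self.t_end:
            return self.segments[-1][2]
        raise ValueError(f"t={t} outside schedule [{self.t_start}, {self.t_end}]")

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Interior segment boundaries strictly inside (t0, t1)."""
        return [s[0] for s in self.segments[1:] if t0 < s[0] < t1]
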