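"""Semi-landmark sampling scheme for the occlusal enamel outline.

The digitization protocol places 8 fixed landmarks on the enamel outline and
draws 8 curves, one between each pair of consecutive landmarks.  Each curve is
resampled to a fixed number of equidistant semi-landmarks, 178 in total by
default, giving configurations of 8 + 178 = 186 points.

Point order convention: the 8 fixed landmarks first (indices 0..7), then the
semi-landmarks of curve 0, curve 1, ... curve 7.  Curve ``c`` runs from fixed
landmark ``c`` to fixed landmark ``(c + 1) % 8``, so the landmarks anchor the
ends of every sliding chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Default per-curve semi-landmark counts.  The protocol fixes only the total
#: (178); the split across the eight curves is configurable.
DEFAULT_COUNTS: tuple[int, ...] = (22, 22, 22, 22, 22, 22, 23, 23)

N_LANDMARKS = 8
N_CURVES = 8


@dataclass(frozen=True)
class SemiLandmarkScheme:
    """Maps (landmark / curve, within-curve index) to flat point indices.

    Attributes
    ----------
    counts_per_curve:
        Number of semi-landmarks sampled on each of the 8 curves.
    """

    counts_per_curve: tuple[int, ...] = DEFAULT_COUNTS
    n_landmarks: int = field(default=N_LANDMARKS)

    def __post_init__(self) -> None:
        if len(self.counts_per_curve) != N_CURVES:
            raise ValueError(
                f"expected {N_CURVES} per-curve counts, got {len(self.counts_per_curve)}"
            )
        if any(c < 1 for c in self.counts_per_curve):
            raise ValueError("every curve needs at least one semi-landmark")

    @property
    def total_semilandmarks(self) -> int:
        return sum(self.counts_per_curve)

    @property
    def n_points(self) -> int:
        """Total points per configuration (landmarks + semi-landmarks)."""
        return self.n_landmarks + self.total_semilandmarks

    def curve_start(self, curve: int) -> int:
        """Flat index of the first semi-landmark of ``curve``."""
        return self.n_landmarks + sum(self.counts_per_curve[:curve])

    def flat_index(self, curve: int, within: int) -> int:
        if not 0 <= within < self.counts_per_curve[curve]:
            raise IndexError(f"semi-landmark {within} out of range for curve {curve}")
        return self.curve_start(curve) + within

    def curve_chain(self, curve: int) -> list[int]:
        """Flat indices along curve ``curve`` including its two anchor landmarks."""
        start = self.curve_start(curve)
        m = self.counts_per_curve[curve]
        return [curve, *range(start, start + m), (curve + 1) % self.n_landmarks]

    @property
    def semilandmark_indices(self) -> list[int]:
        return list(range(self.n_landmarks, self.n_points))

    @property
    def slider_triplets(self) -> list[tuple[int, int, int]]:
        """(before, slider, after) triplets, one per semi-landmark.

        Neighbours are the immediately adjacent points along the curve chain;
        fixed landmarks serve as anchors at the curve ends.
        """
        triplets: list[tuple[int, int, int]] = []
        for c in range(N_CURVES):
            chain = self.curve_chain(c)
            for k in range(1, len(chain) - 1):
                triplets.append((chain[k - 1], chain[k], chain[k + 1]))
        return triplets
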