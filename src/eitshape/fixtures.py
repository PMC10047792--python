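"""Scripted test phantoms used across the experiment pipeline.

A small deterministic pack of hand-specified conductivity phantoms that the
baseline comparisons and the reconstruction experiments run on: a single
off-centre inclusion, two disjoint inclusions of opposite contrast, three
inclusions, a ring-like cluster of four, and the homogeneous control.
"""

from __future__ import annotations

from .phantoms import Circle, Phantom

__all__ = ["make_fixtures", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "one_inclusion",
    "two_inclusions",
    "three_inclusions",
    "four_cluster",
    "homogeneous",
)


def make_fixtures() -> dict[str, Phantom]:
    """Deterministic pack of five scripted phantoms keyed by name."""
    return {
        "one_inclusion": Phantom(
            circles=[Circle(center=(0.4, 0.0), radius=0.3, conductivity=2.0)]
        ),
        "two_inclusions": Phantom(
            circles=[
                Circle(center=(-0.4, 0.3), radius=0.25, conductivity=2.0),
                Circle(center=(0.35, -0.35), radius=0.2, conductivity=0.5),
            ]
        ),
        "three_inclusions": Phantom(
            circles=[
                Circle(center=(0.0, 0.5), radius=0.2, conductivity=3.0),
                Circle(center=(-0.45, -0.25), radius=0.18, conductivity=0.4),
                Circle(center=(0.45, -0.25), radius=0.22, conductivity=2.5),
            ]
        ),
        "four_cluster": Phantom(
            circles=[
                Circle(center=(0.35, 0.35), radius=0.15, conductivity=2.0),
                Circle(center=(-0.35, 0.35), radius=0.15, conductivity=2.0),
                Circle(center=(-0.35, -0.35), radius=0.15, conductivity=0.5),
                Circle(center=(0.35, -0.35), radius=0.15, conductivity=2.0),
            ]
        ),
        "homogeneous": Phantom(circles=[]),
    }
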