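"""Shared fixtures: analytic vessel phantoms built from circles and bands."""

import numpy as np
import pytest

from capquant import ClosedContour, SliceContours


def circle_points(radius: float, n: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def annular_band(
    r_in: float, r_out: float, theta_start: float, theta_end: float, n: int = 64
) -> np.ndarray:
    """Polygon of the band r_in..r_out over the arc theta_start..theta_end."""
    th = np.linspace(theta_start, theta_end, n)
    inner = np.column_stack([r_in * np.cos(th), r_in * np.sin(th)])
    outer = np.column_stack([r_out * np.cos(th[::-1]), r_out * np.sin(th[::-1])])
    return np.vstack([inner, outer])


@pytest.fixture
def annulus_slice() -> SliceContours:
    """Concentric lumen r=1.5 / wall R=2.5, no lipid."""
    return SliceContours(
        slice_id="annulus",
        modality="OCT",
        lumen=ClosedContour(circle_points(1.5), "lumen"),
        wall=ClosedContour(circle_points(2.5), "wall"),
        myocardium_angle=0.0,
    )


@pytest.fixture
def annulus_band_slice() -> SliceContours:
    """Annulus with a lipid band 1.7..2.2 mm spanning the 90 deg arc at 0."""
    return SliceContours(
        slice_id="annulus-band",
        modality="OCT",
        lumen=ClosedContour(circle_points(1.5), "lumen"),
        wall=ClosedContour(circle_points(2.5), "wall"),
        lipids=(
            ClosedContour(annular_band(1.7, 2.2, -np.pi / 4, np.pi / 4), "lipid"),
        ),
        myocardium_angle=0.0,
    )


def rigid_transform(slc: SliceContours, angle: float, shift=(0.0, 0.0)) -> SliceContours:
    """Rotate by ``angle`` about the origin and translate, myocardium included."""
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )

    def move(contour: ClosedContour) -> ClosedContour:
        return ClosedContour(contour.points @ rot.T + np.asarray(shift), contour.role)

    return SliceContours(
        slice_id=slc.slice_id,
        modality=slc.modality,
        lumen=move(slc.lumen),
        wall=move(slc.wall),
        lipids=tuple(move(lp) for lp in slc.lipids),
        myocardium_angle=slc.myocardium_angle + angle,
    )
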