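"""SEM-like porous image generator with ground truth.

Dark, slightly elliptical pores on a bright matrix.  Pore diameters are
drawn from a scaled beta distribution, pores are placed without overlap
(with a small guard gap), a row-wise charging gradient and Gaussian sensor
noise are added, and the interior of each pore carries extra speckle so
pore/matrix neighbourhoods differ in texture, not just brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from cryofront.mia import SEMImage


@dataclass
class PoreSpec:
    """Pore population and imaging parameters.

    ``diameter_scale_um`` maps the beta support [0, 1] to physical
    diameters.  ``charging_gradient`` is the intensity ramp per image row
    emulating the charging artefact.
    """

    beta_a: float = 1.2
    beta_b: float = 15.0
    diameter_scale_um: float = 250.0
    n_pores: int = 500
    porosity_target: float = 0.15
    charging_gradient: float = 0.03
    seed: int = 0
    matrix_level: float = 200.0
    pore_level: float = 70.0
    noise_sd: float = 4.0
    pore_texture_sd: float = 12.0
    min_gap_px: int = 3
    ellipticity: float = 0.2

    def __post_init__(self):
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not 0 < self.porosity_target < 1:
            raise ValueError("porosity_target must be in (0, 1)")
        if self.n_pores < 1:
            raise ValueError("n_pores must be >= 1")


def generate_sem_image(
    spec: PoreSpec,
    image_shape: tuple[int, int] = (1024, 1088),
    px_size_um: float = 1.0,
    cake_level: str = "MIDDLE",
    sample_id: str = "synthetic",
    max_attempts: int = 200,
    return_mask: bool = False,
) -> tuple[SEMImage, pd.DataFrame]:
    """Generate one image and its ground-truth pore table.

    Pores are placed until ``spec.porosity_target`` is reached or
    ``spec.n_pores`` have been drawn; a pore that cannot be placed without
    overlap after ``max_attempts`` random positions raises ``ValueError``
    (porosity unreachable).  Fully deterministic for a fixed spec.  With
    ``return_mask`` the ground-truth label matrix is returned as well.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = image_shape
    n_px = rows * cols

    diam_um = spec.diameter_scale_um * rng.beta(spec.beta_a, spec.beta_b,
                                                size=spec.n_pores)
    diam_px = diam_um / px_size_um

    occupancy = np.zeros(image_shape, dtype=bool)   # pores + guard gap
    pore_mask = np.zeros(image_shape, dtype=bool)
    labels = np.zeros(image_shape, dtype=np.int32)
    records = []
    placed_area = 0
    gap = spec.min_gap_px

    # largest-first placement: big pores need contiguous free space, so
    # placing them into an empty field makes crowding failures rare
    for i in np.argsort(-diam_px):
        d = diam_px[i]
        if placed_area / n_px >= spec.porosity_target:
            break
        r = max(d / 2.0, 0.7)
        squeeze = 1.0 + spec.ellipticity * rng.uniform(-1.0, 1.0)
        r_row, r_col = r * squeeze, r / squeeze
        theta = rng.uniform(0.0, np.pi)
        placed = False
        for _ in range(max_attempts):
            cr = rng.uniform(r_row + gap, rows - r_row - gap)
            cc = rng.uniform(r_col + gap, cols - r_col - gap)
            rr, ccx = ellipse(cr, cc, r_row, r_col, shape=image_shape,
                              rotation=theta)
            if rr.size == 0 or occupancy[rr, ccx].any():
                continue
            grr, gcc = ellipse(cr, cc, r_row + gap, r_col + gap,
                               shape=image_shape, rotation=theta)
            occupancy[grr, gcc] = True
            pore_mask[rr, ccx] = True
            labels[rr, ccx] = len(records) + 1
            area = int(rr.size)
            placed_area += area
            records.append({
                "pore_id": len(records) + 1,
                "area_px": area,
                "eq_diameter_um": px_size_um * np.sqrt(4.0 * area / np.pi),
                "diameter_drawn_um": float(diam_um[i]),
                "centroid_row": float(cr),
                "centroid_col": float(cc),
            })
            placed = True
            break
        if not placed:
            raise ValueError(
                f"porosity target {spec.porosity_target} unreachable: pore "
                f"{i} (d={d:.1f} px) could not be placed after "
                f"{max_attempts} attempts")

    img = np.full(image_shape, spec.matrix_level, dtype=float)
    img[pore_mask] = spec.pore_level
    if spec.pore_texture_sd > 0 and pore_mask.any():
        img[pore_mask] += rng.normal(0.0, spec.pore_texture_sd,
                                     size=int(pore_mask.sum()))
    img += spec.charging_gradient * (np.arange(rows)[:, None] - rows / 2.0)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=image_shape)
    img = np.clip(img, 0.0, 255.0)

    ground_truth = pd.DataFrame(
        records,
        columns=["pore_id", "area_px", "eq_diameter_um", "diameter_drawn_um",
                 "centroid_row", "centroid_col"],
    )
    ground_truth["sample_id"] = sample_id
    ground_truth["cake_level"] = cake_level
    image = SEMImage(intensity=img, px_size_um=px_size_um,
                     cake_level=cake_level, sample_id=sample_id)
    if return_mask:
        return image, ground_truth, labels
    return image, ground_truth
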