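"""Shared fixtures: digitized spheres and segmented synthetic embryos.

The expensive imaging fixtures (render -> preprocess -> region growing) are
session-scoped so that volume-recovery, QC and plate-geometry tests share
one segmentation run per condition.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blastovol import plate, segmentation as seg, synthetic as syn, volumetry as vol
from blastovol.stacks import DEFAULT_SPACING, LabelMap

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def digitized_sphere(radius: float, spacing=DEFAULT_SPACING,
                     center=None, sub_voxel: float = 0.0) -> tuple[LabelMap, np.ndarray]:
    """Label map of a voxelised sphere; ``sub_voxel`` offsets the centre in x
    by a fraction of L_x to probe grid-alignment effects."""
    spacing = np.asarray(spacing, dtype=float)
    if center is None:
        center = np.array([
            round((radius + 2) / spacing[0]) * spacing[0],
            radius + 2.0,
            radius + 2.0 + sub_voxel * spacing[2],
        ])
    shape = tuple(int((c + radius + 2) / s) + 1 for c, s in zip(center, spacing))
    zz = (np.arange(shape[0]) * spacing[0])[:, None, None]
    yy = (np.arange(shape[1]) * spacing[1])[None, :, None]
    xx = (np.arange(shape[2]) * spacing[2])[None, None, :]
    m = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
         + (xx - center[2]) ** 2) <= radius ** 2
    return LabelMap(m.astype(np.int32), spacing=tuple(spacing)), center


def _segment_division_pair(noise: syn.NoiseSettings, seed: int):
    before, after = syn.division_pair_embryos(mother_radius=9.0, shift=1.75)
    out = {}
    for tag, truth, s in (("before", before, seed), ("after", after, seed + 1)):
        mem, _ = syn.render_embryo_stack(truth, noise=noise, seed=s)
        names, coords = syn.seeds_from_truth(truth)
        pre = seg.preprocess(mem)
        lm = seg.grow_seeds(pre, seg.SeedSet(names, coords), rng_seed=s + 100)
        out[tag] = dict(
            truth={c.name: c.volume for c in truth.cells},
            segmented=vol.volumes_by_name(lm),
            labelmap=lm,
            stack=mem,
        )
    return out


@pytest.fixture(scope="session")
def segmented_division_noiseless():
    """Mother and daughter stacks, rendered without noise and segmented."""
    return _segment_division_pair(syn.NoiseSettings(additive_sigma=0.0), seed=11)


@pytest.fixture(scope="session")
def segmented_division_noisy():
    """Same embryos with default camera noise."""
    return _segment_division_pair(syn.NoiseSettings(), seed=23)


@pytest.fixture(scope="session")
def germline_plate_measurements():
    """Plate-displacement measurements on ten synthetic germline cells.

    Cells of radii 4..12 µm are rendered with the default germline plate
    offset (1.36 µm) along a tilted axis, segmented, and measured with the
    cortical-centre / division-normal / projection pipeline.
    """
    axis = np.array([0.25, 0.35, 0.9])
    axis /= np.linalg.norm(axis)
    rng = np.random.default_rng(2024)
    rows = []
    for i, radius in enumerate(np.linspace(4.0, 12.0, 10)):
        # sub-voxel centre jitter decorrelates grid alignment from radius
        jitter = rng.uniform(0, 1, 3) * np.array(DEFAULT_SPACING)
        truth = syn.single_germline_cell(radius, plate_offset=1.36, axis=axis,
                                         center_jitter=jitter)
        cell = truth.cells[0]
        mem, _ = syn.render_embryo_stack(truth, seed=40 + i)
        names, coords = syn.seeds_from_truth(truth)
        pre = seg.preprocess(mem)
        lm = seg.grow_seeds(pre, seg.SeedSet(names, coords), rng_seed=60 + i)
        r1, r2 = syn.synthetic_track(cell)
        track = plate.ChromatinTrack(r1=r1, r2=r2)
        geom = plate.measure_plate_geometry(lm, 1, track, seed=80 + i)
        rows.append(dict(radius=radius, cell=cell, labelmap=lm,
                         track=track, geometry=geom))
    return rows
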