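"""Optional LIDC-IDRI adapter: DICOM slices + XML nodule annotations.

Maps a directory of CT slices with LIDC-style XML session files onto
the same :class:`~collidernet.imaging.ImagePatch` contract the
synthetic generator uses, so a real image pool can stand in for the
synthetic one without touching the rest of the pipeline.  Requires the
``lidc`` extra (pydicom, lxml); the core package and its tests never
import this module.

Conventions: slices are matched to annotations by SOP instance UID;
when several radiologists segmented the same slice the first reader's
contour is used for feature measurement while ``n_annotations`` counts
the distinct readers, so the all-annotators-agree filter can be
applied downstream.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ImagePatch, ImagePool, filter_pool, measure_features, preprocess

__all__ = ["read_annotations", "build_pool_from_lidc"]

_NS = {"n": "http://www.nih.gov"}


def read_annotations(xml_path) -> dict[str, list[np.ndarray]]:
    """Per-SOP-UID list of contours (one per reading session).

    Each contour is an (n, 2) integer array of (row, col) edge points.
    """
    from lxml import etree

    tree = etree.parse(str(xml_path))
    by_sop: dict[str, list[np.ndarray]] = defaultdict(list)
    for session in tree.findall(".//n:readingSession", _NS):
        for roi in session.findall(".//n:unblindedReadNodule/n:roi", _NS):
            sop = roi.findtext("n:imageSOP_UID", default="", namespaces=_NS)
            pts = [
                (int(e.findtext("n:yCoord", namespaces=_NS)),
                 int(e.findtext("n:xCoord", namespaces=_NS)))
                for e in roi.findall("n:edgeMap", _NS)
            ]
            if sop and pts:
                by_sop[sop].append(np.asarray(pts, dtype=int))
    return dict(by_sop)


def _contour_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled polygon mask from contour edge points."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    rr = np.clip(contour[:, 0], 0, shape[0] - 1)
    cc = np.clip(contour[:, 1], 0, shape[1] - 1)
    mask[rr, cc] = True
    return ndimage.binary_fill_holes(mask)


def build_pool_from_lidc(
    scan_dir,
    min_size_mm2: float = 20.0,
    validation_fraction: float = 0.3,
    split_seed: int = 0,
) -> ImagePool:
    """Walk a LIDC-style directory and assemble an :class:`ImagePool`.

    The train/validation split is drawn at the nodule (source) level so
    the two pools share no nodule.
    """
    import pydicom

    scan_dir = Path(scan_dir)
    annotations: dict[str, list[np.ndarray]] = {}
    for xml_path in scan_dir.rglob("*.xml"):
        annotations.update(read_annotations(xml_path))
    patches: list[ImagePatch] = []
    for dcm_path in sorted(scan_dir.rglob("*.dcm")):
        ds = pydicom.dcmread(str(dcm_path))
        sop = str(getattr(ds, "SOPInstanceUID", ""))
        contours = annotations.get(sop)
        if not contours:
            continue
        pixels = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = pixels * slope + intercept
        spacing = float(ds.PixelSpacing[0])
        mask = _contour_mask(contours[0], pixels.shape)  # first reader's contour
        if not mask.any():
            continue
        patches.append(
            preprocess(
                pixels,
                mask,
                native_spacing_mm=spacing,
                source_id=sop,
                n_annotations=len(contours),
            )
        )
    patches = filter_pool(patches, min_size_mm2=min_size_mm2)
    if not patches:
        raise ValueError(f"no usable annotated slices under {scan_dir}")
    rng = np.random.default_rng(split_seed)
    split = np.where(
        rng.uniform(size=len(patches)) < validation_fraction, "validation", "train"
    )
    rows = []
    for patch, sp in zip(patches, split):
        feat = measure_features(patch)
        rows.append(
            {
                "source_id": patch.source_id,
                "split": sp,
                "x_prime": feat.x_prime,
                "z_prime": feat.z_prime,
            }
        )
    pool = ImagePool(patches, pd.DataFrame(rows))
    # re-standardize intensities with the training split's global moments
    train_stack = np.stack(
        [p.pixels for p, sp in zip(patches, split) if sp == "train"]
    )
    g_mean, g_sd = float(train_stack.mean()), float(train_stack.std()) or 1.0
    for p in patches:
        p.pixels = (p.pixels - g_mean) / g_sd
    refreshed = [
        {**row, "z_prime": measure_features(p).z_prime}
        for row, p in zip(rows, patches)
    ]
    pool = ImagePool(patches, pd.DataFrame(refreshed))
    pool.log_stats["global_mean"] = g_mean
    pool.log_stats["global_sd"] = g_sd
    return pool
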