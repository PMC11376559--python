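"""Handcrafted histology features per spot.

For each spot a square patch centred on its pixel coordinate is cut from
the stained image. The grayscale patch is contrast-normalized with CLAHE
(contrast-limited adaptive histogram equalization), quantized to 64 gray
levels, and summarized by a gray-level co-occurrence matrix (distance 1,
four angles averaged, symmetric, normalized). Six GLCM statistics —
contrast, dissimilarity, homogeneity, angular second moment, entropy and
correlation — plus the raw patch's mean R/G/B intensities give a
9-dimensional feature vector per spot.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops

from .types import HistologyFeatures, SpatialSection

__all__ = ["extract_histology_features", "glcm_statistics",
           "save_histology_features", "load_histology_features", "GLCM_LEVELS"]

GLCM_LEVELS = 64
_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def glcm_statistics(gray_levels: np.ndarray, levels: int = GLCM_LEVELS) -> dict[str, float]:
    """Six GLCM statistics of an integer-quantized grayscale patch.

    The co-occurrence matrix uses distance 1 at angles 0/45/90/135
    degrees, symmetric and normalized; statistics are averaged over the
    angles. Entropy is -sum p log2 p over nonzero cells.
    """
    glcm = graycomatrix(gray_levels.astype(np.uint8), distances=[1],
                        angles=list(_ANGLES), levels=levels,
                        symmetric=True, normed=True)
    out = {}
    for prop in ("contrast", "dissimilarity", "homogeneity", "ASM",
                 "correlation"):
        out[prop] = float(graycoprops(glcm, prop)[0].mean())
    p = glcm[:, :, 0, :]
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    out["entropy"] = float(-(p * logp).sum(axis=(0, 1)).mean())
    return out


def _quantize(img01: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    return np.clip((img01 * levels).astype(int), 0, levels - 1)


def extract_histology_features(section: SpatialSection,
                               patch_px: int | None = 50,
                               clahe_clip: float = 0.01) -> HistologyFeatures:
    """Extract the 9 per-spot image features.

    ``patch_px`` is the side of the square patch; pass ``None`` to size
    patches from the section's spot diameter when known (falling back to
    50 px). Patches are clipped at image borders.
    """
    if section.image is None:
        raise ValueError(
            "section has no tissue image; run the two-view ablation "
            "(views spatial,expression) instead")
    if patch_px is None:
        patch_px = int(round(section.spot_diameter)) if section.spot_diameter else 50
    if patch_px < 2:
        raise ValueError("patch_px must be at least 2")
    img = np.asarray(section.image)
    h, w = img.shape[:2]
    half = patch_px // 2

    feats = np.zeros((section.n_spots, 9))
    for i, (y, x) in enumerate(section.coords):
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(
                f"spot {section.spot_ids[i]} at ({y:.0f}, {x:.0f}) lies "
                f"outside the {h}x{w} image")
        y0, y1 = max(int(y) - half, 0), min(int(y) + half + 1, h)
        x0, x1 = max(int(x) - half, 0), min(int(x) + half + 1, w)
        patch = img[y0:y1, x0:x1]
        gray = rgb2gray(patch)
        if gray.max() > gray.min():
            gray = exposure.equalize_adapthist(gray, clip_limit=clahe_clip)
        stats = glcm_statistics(_quantize(gray))
        feats[i, :6] = [stats[name] for name in
                        ("contrast", "dissimilarity", "homogeneity", "ASM",
                         "entropy", "correlation")]
        feats[i, 6:] = patch.reshape(-1, 3).mean(axis=0)
    return HistologyFeatures(F=feats, spot_ids=list(section.spot_ids))


def save_histology_features(hfeat: HistologyFeatures, path) -> None:
    """Write features as CSV: spot_id column plus one column per feature."""
    import pandas as pd

    df = pd.DataFrame(hfeat.F, columns=hfeat.feature_names)
    df.insert(0, "spot_id", hfeat.spot_ids)
    df.to_csv(path, index=False)


def load_histology_features(path) -> HistologyFeatures:
    import pandas as pd

    df = pd.read_csv(path)
    return HistologyFeatures(
        F=df.drop(columns="spot_id").to_numpy(float),
        spot_ids=df["spot_id"].astype(str).tolist(),
        feature_names=[c for c in df.columns if c != "spot_id"])
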