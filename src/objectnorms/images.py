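"""Image statistics and network-layer activation entropy.

Simple per-image statistics: circular-mean hue, mean saturation and value,
proportion of non-white pixels, spectral image energy, and encoded JPEG size
as an indirect complexity measure. Complex statistics: Shannon entropy of a
rectified network-layer activation vector (early/middle/late layers), a
scale-invariant summary of how distributed the layer response is.

Notes on conventions (the analysis pins these and writes them to the output
sidecar):

* white threshold 250/255 per channel; a pixel is "white" when all three
  channels are at or above it,
* grayscale via ITU-R BT.601 luma weights (0.299, 0.587, 0.114) on [0, 1],
* energy is the mean squared magnitude of the discrete Fourier spectrum
  excluding the DC component, normalized per pixel — by Parseval's theorem
  this equals the grayscale pixel variance, and a unit-amplitude sinusoidal
  grating has energy 1/2,
* JPEG quality 75, baseline encoder, 4:2:0 chroma subsampling, no metadata,
* activation entropy is computed on the L1-normalized activation vector in
  bits; negatives are clipped to zero first.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2hsv

DEFAULT_WHITE_THRESHOLD = 250
DEFAULT_JPEG_QUALITY = 75
LAYER_NAMES = ("early", "middle", "late")

_LUMA = np.array([0.299, 0.587, 0.114])


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("expected an H x W x 3 RGB array with positive dimensions")
    return img


def _to_unit(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return img.astype(float)


def _white_pixel_mask(img: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean mask of background-white pixels (all channels >= threshold)."""
    u8 = img if img.dtype == np.uint8 else np.clip(np.asarray(img) * 255, 0, 255)
    return (u8 >= threshold).all(axis=2)


def compute_hsv(
    img: np.ndarray,
    white_mask: bool = False,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
) -> tuple[float, float, float]:
    """Mean hue (circular), saturation, and value of an RGB image.

    Hue is an angle, so it is averaged circularly (mean resultant direction
    of the per-pixel hue angles, mapped back to [0, 1)); saturation and value
    are plain means on [0, 1]. With ``white_mask`` the white background
    pixels are excluded; masking away every pixel is an error.
    """
    img = _validate_rgb(img)
    hsv = rgb2hsv(_to_unit(img))
    if white_mask:
        keep = ~_white_pixel_mask(img, white_threshold)
        if not keep.any():
            raise ValueError("white mask removed every pixel; HSV undefined")
        hsv = hsv[keep]
    else:
        hsv = hsv.reshape(-1, 3)
    angles = hsv[:, 0] * 2 * np.pi
    s, c = np.sin(angles).mean(), np.cos(angles).mean()
    if s == 0 and c == 0:
        hue = 0.0
    else:
        hue = (np.arctan2(s, c) / (2 * np.pi)) % 1.0
    return float(hue), float(hsv[:, 1].mean()), float(hsv[:, 2].mean())


def proportion_nonwhite(
    img: np.ndarray, threshold: int = DEFAULT_WHITE_THRESHOLD
) -> float:
    """Fraction of pixels with any channel below the white threshold."""
    img = _validate_rgb(img)
    return float((~_white_pixel_mask(img, threshold)).mean())


def image_energy(img: np.ndarray) -> float:
    """Spectral energy: mean squared non-DC Fourier magnitude per pixel.

    Computed on the BT.601 grayscale image in [0, 1]. Equals the grayscale
    variance (Parseval), so a constant image has energy exactly 0.
    """
    img = _validate_rgb(img)
    gray = _to_unit(img) @ _LUMA
    F = np.fft.fft2(gray)
    n = gray.size
    total = (np.abs(F) ** 2).sum()
    dc = np.abs(F[0, 0]) ** 2
    return float(max(total - dc, 0.0) / n**2)


def jpeg_complexity(img: np.ndarray, quality: int = DEFAULT_JPEG_QUALITY) -> int:
    """Byte length of the image encoded as baseline JPEG at fixed settings."""
    img = _validate_rgb(img)
    if not 1 <= quality <= 100:
        raise ValueError("quality must be in [1, 100]")
    u8 = img if img.dtype == np.uint8 else np.clip(np.asarray(img) * 255, 0, 255).astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(u8, mode="RGB").save(
        buf, format="JPEG", quality=quality, subsampling=2, optimize=False, progressive=False
    )
    return buf.getbuffer().nbytes


def activation_entropy(values: np.ndarray, method: str = "normalized", bins: int = 32) -> float:
    """Shannon entropy (bits) of a rectified layer-activation vector.

    ``method="normalized"`` (default): negatives are clipped to zero, the
    vector is L1-normalized into a distribution over units, and
    ``H = -sum p log2 p``. Scale-invariant, 0 for a one-hot vector, log2(K)
    for a uniform one. ``method="histogram"``: entropy of the equal-width
    histogram of activation values (``bins`` bins), for users who prefer a
    binned estimator.
    """
    v = np.clip(np.asarray(values, dtype=float).ravel(), 0, None)
    if v.size == 0 or v.sum() <= 0:
        raise ValueError("activation entropy undefined: no positive entries")
    if method == "normalized":
        p = v / v.sum()
    elif method == "histogram":
        counts, _ = np.histogram(v, bins=bins)
        if counts.sum() == 0:
            raise ValueError("empty histogram")
        p = counts / counts.sum()
    else:
        raise ValueError(f"unknown entropy method {method!r}")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def simple_image_stats(
    img: np.ndarray,
    white_mask: bool = False,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
    jpeg_quality: int = DEFAULT_JPEG_QUALITY,
) -> dict[str, float]:
    """All simple statistics for one image as a flat dict."""
    hue, sat, val = compute_hsv(img, white_mask=white_mask, white_threshold=white_threshold)
    return {
        "hue": hue,
        "saturation": sat,
        "value": val,
        "prop_nonwhite": proportion_nonwhite(img, threshold=white_threshold),
        "energy": image_energy(img),
        "jpeg_size": jpeg_complexity(img, quality=jpeg_quality),
    }


# ---------------------------------------------------------------------------
# activation persistence: one CSV per layer, first column image_id


def save_activations(out_dir: str | Path, layers: dict[str, tuple[list[str], np.ndarray]]) -> None:
    """Write per-layer activation matrices as CSV (image_id + unit columns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, (ids, arr) in layers.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != len(ids):
            raise ValueError(f"layer {layer!r}: need one row per image id")
        df = pd.DataFrame(arr, columns=[f"u{i}" for i in range(arr.shape[1])])
        df.insert(0, "image_id", list(ids))
        df.to_csv(out / f"layer_{layer}.csv", index=False)


def load_activations(in_dir: str | Path) -> dict[str, tuple[list[str], np.ndarray]]:
    """Load activation CSVs written by :func:`save_activations`.

    Validates that every layer's vectors share one length and that values are
    usable post-rectification (at least one positive entry per row).
    """
    src = Path(in_dir)
    layers = {}
    for path in sorted(src.glob("layer_*.csv")):
        layer = path.stem[len("layer_"):]
        df = pd.read_csv(path)
        if "image_id" not in df.columns:
            raise ValueError(f"{path.name}: missing image_id column")
        arr = df.drop(columns=["image_id"]).to_numpy(dtype=float)
        if (np.clip(arr, 0, None).sum(axis=1) <= 0).any():
            raise ValueError(f"{path.name}: row with no positive activation")
        layers[layer] = (df["image_id"].astype(str).tolist(), arr)
    if not layers:
        raise FileNotFoundError(f"no layer_*.csv files under {src}")
    return layers


def extract_activations(images, layers=(3, 6, 8)):
    """Optional adapter: activations from a pretrained classification network.

    Requires ``torchvision`` with pretrained weights available; it is an
    optional extra and nothing in this package depends on it — synthetic
    activations (:mod:`objectnorms.synth`) serve the same interface.
    """
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "extract_activations needs torch/torchvision; install them or use "
            "synthetic activations from objectnorms.synth.generate_activations"
        ) from exc
    raise NotImplementedError(
        "pretrained-network extraction is left to deployment environments with "
        "network weights; see docs/methods.md"
    )  # pragma: no cover


def profile_images(
    images: dict[str, np.ndarray],
    activations: dict[str, tuple[list[str], np.ndarray]] | None = None,
    white_mask: bool = False,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
    jpeg_quality: int = DEFAULT_JPEG_QUALITY,
    entropy_method: str = "normalized",
) -> pd.DataFrame:
    """Per-image statistics table, optionally with per-layer entropies.

    ``activations`` maps layer name -> (image ids, activation matrix); layer
    entropies appear as columns ``H_<layer>``.
    """
    rows = {}
    for image_id, img in images.items():
        rows[image_id] = simple_image_stats(
            img, white_mask=white_mask, white_threshold=white_threshold,
            jpeg_quality=jpeg_quality,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "image_id"
    if activations:
        for layer, (ids, arr) in activations.items():
            H = pd.Series(
                [activation_entropy(arr[i], method=entropy_method) for i in range(len(ids))],
                index=ids, name=f"H_{layer}",
            )
            out[f"H_{layer}"] = H.reindex(out.index)
    return out


def write_profile(out_path: str | Path, profile: pd.DataFrame, params: dict) -> None:
    """Write the per-image table plus a JSON sidecar of pinned parameters."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    profile.to_csv(out_path)
    out_path.with_suffix(".json").write_text(json.dumps(params, indent=1))
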