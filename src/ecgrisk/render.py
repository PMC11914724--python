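"""Paper-format ECG page rendering.

Reproduces the two image dialects the pipeline must handle: a hospital-style
colour page (4x3 panel of 2.5-s leads, optional 10-s rhythm strips below, red
millimetre grid) and a plain rendered image with or without grid. Drawing is
done directly with Pillow so every sample's pixel position is known exactly;
that geometry is kept as ground truth on synthetic renders and is what the
digitizer is tested against.

Scale conventions are the clinical standard: 25 mm/s paper speed and
10 mm/mV gain, one small grid box = 1 mm. Image origin is top-left with y
increasing downward, so positive millivolts deflect toward smaller rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage

from .signals import ECGSignal, LEAD_NAMES

#: Standard printed order: columns left→right, rows top→bottom.
DEFAULT_LEAD_GRID = {
    "I": (0, 0), "II": (1, 0), "III": (2, 0),
    "aVR": (0, 1), "aVL": (1, 1), "aVF": (2, 1),
    "V1": (0, 2), "V2": (1, 2), "V3": (2, 2),
    "V4": (0, 3), "V5": (1, 3), "V6": (2, 3),
}


@dataclass(frozen=True)
class LayoutSpec:
    """Paper-format geometry: panel shape, time per column, print scales."""

    columns: int = 4
    rows: int = 3
    seconds_per_column: float = 2.5
    rhythm_leads: tuple[str, ...] = ("II", "V1", "V5")
    paper_speed: float = 25.0  # mm/s
    gain: float = 10.0  # mm/mV
    lead_grid: dict = field(default_factory=lambda: dict(DEFAULT_LEAD_GRID))

    def __post_init__(self) -> None:
        if self.columns * self.rows != 12:
            raise ValueError("columns x rows must equal 12")
        if len(self.rhythm_leads) > 3:
            raise ValueError("at most 3 rhythm strips")
        unknown = set(self.rhythm_leads) - set(LEAD_NAMES)
        if unknown:
            raise ValueError(f"unknown rhythm lead(s): {unknown}")
        if set(self.lead_grid) != set(LEAD_NAMES):
            raise ValueError("lead_grid must place all 12 leads")

    @property
    def panel_duration(self) -> float:
        return self.columns * self.seconds_per_column

    def lead_columns(self) -> dict[str, int]:
        """Lead → column index, for asynchronous masking."""
        return {name: rc[1] for name, rc in self.lead_grid.items()}


@dataclass(frozen=True)
class RenderStyle:
    """Page size, pixel density, grid and colouring."""

    width: int = 2200
    height: int = 1700
    px_per_mm: float = 8.0
    grid: bool = True
    color: bool = True
    trace_width: int = 2
    labels: bool = True
    # colour dialect: light red grid, black trace (hospital-style page)
    minor_grid_rgb: tuple[int, int, int] = (255, 200, 200)
    major_grid_rgb: tuple[int, int, int] = (255, 150, 150)
    # greyscale dialect grid intensities
    minor_grid_grey: int = 215
    major_grid_grey: int = 185

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")


@dataclass
class RenderedECG:
    """A rasterized page plus (for synthetic renders) ground-truth geometry."""

    pixels: np.ndarray  # (H, W) grey or (H, W, 3) colour, uint8
    truth: dict | None = None

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def to_png(self, path: str | Path, with_truth: bool = True) -> None:
        Image.fromarray(self.pixels).save(path)
        if with_truth and self.truth is not None:
            Path(path).with_suffix(".json").write_text(json.dumps(self.truth))

    @classmethod
    def from_png(cls, path: str | Path) -> "RenderedECG":
        img = Image.open(path)
        arr = np.asarray(img.convert("RGB" if img.mode not in ("L", "1") else "L"))
        sidecar = Path(path).with_suffix(".json")
        truth = json.loads(sidecar.read_text()) if sidecar.exists() else None
        return cls(arr.copy(), truth)


def _page_geometry(layout: LayoutSpec, style: RenderStyle) -> dict:
    px_per_s = layout.paper_speed * style.px_per_mm
    panel_w = int(round(layout.panel_duration * px_per_s))
    if panel_w > style.width:
        raise ValueError(
            f"panel ({panel_w} px) wider than page ({style.width} px); "
            "reduce px_per_mm or page duration"
        )
    x0 = (style.width - panel_w) // 2
    n_bands = layout.rows + len(layout.rhythm_leads)
    top, bottom = 120, 80
    band_px = min((style.height - top - bottom) // n_bands, int(32 * style.px_per_mm))
    if band_px < 8 * style.px_per_mm:
        raise ValueError("page too short for the configured layout")
    return {
        "px_per_s": px_per_s, "panel_w": panel_w, "x0": x0,
        "top": top, "band_px": band_px, "n_bands": n_bands,
    }


def render_paper_ecg(signal: ECGSignal, layout: LayoutSpec | None = None,
                     style: RenderStyle | None = None) -> RenderedECG:
    """Draw a 12-lead signal as a paper-format page.

    Each lead occupies its layout cell and shows the 2.5-s slice of the
    recording belonging to its column (asynchronous timing); configured
    rhythm leads are drawn as full-duration strips below the panel. The
    returned truth dict records pixel scales, per-lead baseline rows and
    window boxes, and the panel bounding box.
    """
    layout = layout or LayoutSpec()
    style = style or RenderStyle()
    if signal.duration < layout.panel_duration - 1e-9:
        raise ValueError(
            f"signal duration {signal.duration:g}s shorter than layout's "
            f"{layout.panel_duration:g}s"
        )
    geo = _page_geometry(layout, style)
    px_per_s, x0, top, band_px = geo["px_per_s"], geo["x0"], geo["top"], geo["band_px"]
    mv_px = layout.gain * style.px_per_mm  # px per mV, upward

    bg = (255, 255, 255) if style.color else 255
    img = Image.new("RGB" if style.color else "L", (style.width, style.height), bg)
    draw = ImageDraw.Draw(img)

    if style.grid:
        minor = style.minor_grid_rgb if style.color else style.minor_grid_grey
        major = style.major_grid_rgb if style.color else style.major_grid_grey
        n_x = int(style.width / style.px_per_mm) + 1
        n_y = int(style.height / style.px_per_mm) + 1
        for k in range(n_x):
            x = int(round(k * style.px_per_mm))
            draw.line([(x, 0), (x, style.height)], fill=major if k % 5 == 0 else minor)
        for k in range(n_y):
            y = int(round(k * style.px_per_mm))
            draw.line([(0, y), (style.width, y)], fill=minor if k % 5 else major)

    trace = (0, 0, 0) if style.color else 0
    font = ImageFont.load_default()
    truth_leads: dict[str, dict] = {}

    def draw_trace(samples: np.ndarray, t_start: float, t_end: float,
                   baseline: float, x_start: float) -> None:
        i0 = int(round(t_start * signal.fs))
        i1 = min(int(round(t_end * signal.fs)), samples.size)
        seg = samples[i0:i1]
        ts = (np.arange(i0, i1) / signal.fs) - t_start
        xs = x_start + ts * px_per_s
        ys = baseline - seg * mv_px
        pts = list(zip(xs.tolist(), ys.tolist()))
        draw.line(pts, fill=trace, width=style.trace_width, joint="curve")

    for name, (row, col) in layout.lead_grid.items():
        baseline = top + (row + 0.5) * band_px
        t_lo = col * layout.seconds_per_column
        t_hi = t_lo + layout.seconds_per_column
        x_start = x0 + t_lo * px_per_s
        draw_trace(signal.lead(name), t_lo, t_hi, baseline, x_start)
        if style.labels:
            draw.text((x_start + 6, baseline - 0.45 * band_px), name, fill=trace, font=font)
        truth_leads[name] = {
            "row": row, "col": col, "baseline_row": baseline,
            "x_start": x_start, "x_end": x_start + layout.seconds_per_column * px_per_s,
            "t_offset": t_lo,
        }

    strip_baselines = []
    for i, name in enumerate(layout.rhythm_leads):
        baseline = top + (layout.rows + i + 0.5) * band_px
        draw_trace(signal.lead(name), 0.0, layout.panel_duration, baseline, x0)
        if style.labels:
            draw.text((x0 + 6, baseline - 0.45 * band_px), name, fill=trace, font=font)
        strip_baselines.append(baseline)

    panel_bottom = top + layout.rows * band_px
    truth = {
        "px_per_mm": style.px_per_mm,
        "px_per_s": px_per_s,
        "mv_per_px": 1.0 / mv_px,
        "x0": x0,
        "band_px": band_px,
        "panel_box": [top, x0, panel_bottom, x0 + geo["panel_w"]],
        "leads": truth_leads,
        "strip_baselines": strip_baselines,
        "grid": style.grid,
        "fs": signal.fs,
    }
    return RenderedECG(np.asarray(img).copy(), truth)


def apply_scan_degradation(image: RenderedECG, rotation: float = 0.0,
                           blur_sd: float = 0.0, noise_sd: float = 0.0,
                           seed: int = 0) -> RenderedECG:
    """Simulate print-and-scan artefacts: small rotation, blur, pixel noise.

    Output dimensions are unchanged and the result is deterministic given
    ``seed``. All-zero parameters return the input pixels unchanged.
    """
    if rotation < 0 or blur_sd < 0 or noise_sd < 0:
        raise ValueError("degradation parameters must be >= 0")
    arr = image.pixels.astype(float)
    if rotation > 0:
        arr = ndimage.rotate(arr, rotation, axes=(1, 0), reshape=False,
                             order=1, mode="constant", cval=255.0)
    if blur_sd > 0:
        sigma = (blur_sd, blur_sd) + ((0,) if arr.ndim == 3 else ())
        arr = ndimage.gaussian_filter(arr, sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    out = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    truth = dict(image.truth, degraded=True) if image.truth else None
    return RenderedECG(out, truth)


def crop_rhythm_strips(image: RenderedECG, layout: LayoutSpec | None = None) -> RenderedECG:
    """Return only the 4x3 panel region, removing rhythm strips below it.

    Synthetic renders carry the exact panel box in their truth metadata;
    otherwise the panel is located from the detected trace baselines. An
    image without strips is returned unchanged.
    """
    layout = layout or LayoutSpec()
    if image.truth is not None:
        if not image.truth.get("strip_baselines"):
            return image
        top, left, bottom, right = (int(round(v)) for v in image.truth["panel_box"])
        pixels = image.pixels[top:bottom, left:right].copy()
        truth = dict(image.truth)
        truth["panel_box"] = [0, 0, bottom - top, right - left]
        truth["x0"] = image.truth["x0"] - left
        truth["strip_baselines"] = []
        truth["leads"] = {
            name: {**d,
                   "baseline_row": d["baseline_row"] - top,
                   "x_start": d["x_start"] - left,
                   "x_end": d["x_end"] - left}
            for name, d in image.truth["leads"].items()
        }
        truth["cropped"] = True
        return RenderedECG(pixels, truth)

    from .digitize import detect_baseline_rows, trace_mask_of  # lazy: avoid cycle

    mask = trace_mask_of(image)
    baselines = detect_baseline_rows(mask, max_rows=layout.rows + len(layout.rhythm_leads))
    if len(baselines) <= layout.rows:
        return image
    panel = baselines[: layout.rows]
    band = int(np.median(np.diff(baselines))) if len(baselines) > 1 else image.shape[0] // 6
    cols = np.where(mask.any(axis=0))[0]
    top = max(0, int(panel[0] - 0.5 * band))
    bottom = min(image.shape[0], int(panel[-1] + 0.5 * band))
    left, right = int(cols[0]), int(cols[-1]) + 1
    return RenderedECG(image.pixels[top:bottom, left:right].copy(), None)
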