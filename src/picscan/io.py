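"""Reading and writing slide rasters, ground-truth tables and configs.

Slides are stored as multi-page 16-bit TIFF (one page per channel, in the
fixed order DAPI, CK, CD45, brightfield) with the channel names and pixel
scale in the ImageDescription tag as JSON.  Ground truth and event tables
are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError
from .simulate import CHANNELS, GroundTruth, SimConfig, SlideImage, config_from_dict, config_to_dict


def write_slide(path, slide: SlideImage) -> None:
    meta = {"channels": list(slide.channels), "pixel_scale": slide.pixel_scale}
    pages = np.stack([slide.channels[ch] for ch in slide.channels])
    tifffile.imwrite(path, pages, photometric="minisblack",
                     planarconfig="separate", description=json.dumps(meta))


def read_slide(path) -> SlideImage:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        names = meta["channels"]
        pixel_scale = float(meta["pixel_scale"])
    except (TypeError, KeyError, json.JSONDecodeError) as exc:
        raise ConfigurationError(
            f"{path}: missing channel/pixel-scale metadata; was this written "
            "by write_slide?") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if len(names) != pages.shape[0]:
        raise ConfigurationError(f"{path}: {len(names)} channel names for "
                                 f"{pages.shape[0]} pages")
    channels = {name: pages[i] for i, name in enumerate(names)}
    return SlideImage(channels=channels, pixel_scale=pixel_scale)


def write_ground_truth(path, gt: GroundTruth) -> None:
    df = gt.objects.copy()
    df.attrs = {}
    df.to_csv(path, index=False)
    side = Path(path).with_suffix(".meta.json")
    side.write_text(json.dumps({"height": gt.shape[0], "width": gt.shape[1],
                                "pixel_scale": gt.pixel_scale}))


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path)
    df["pair_id"] = df["pair_id"].astype("Int64")
    side = Path(path).with_suffix(".meta.json")
    meta = json.loads(side.read_text())
    return GroundTruth(df, (meta["height"], meta["width"]), meta["pixel_scale"])


def write_sim_config(path, config: SimConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_sim_config(path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


__all__ = [
    "CHANNELS", "write_slide", "read_slide", "write_ground_truth",
    "read_ground_truth", "write_sim_config", "read_sim_config",
]
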