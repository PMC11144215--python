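"""End-to-end screening device orchestration.

Runs the full pipeline on one slide — metadata gates, image read
checks, tile QC, feature extraction, attention inference, likelihood
thresholding and optional 3-tier assignment — and maps every failure
mode to one of the six exact user-facing error messages. The device
never raises for those expected conditions; it returns a
:class:`DeviceResult` whose ``error_message`` is byte-identical to the
contract string.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import pandas as pd

from .errors import (
    DeviceError,
    MetadataError,
    MSG_DISEASE_STAGE,
    MSG_TISSUE_SITE,
)
from .features import HandcraftedBackbone, extract_features
from .mil import MILModel, predict_slide
from .qc import DEFAULT_QC_CONFIG, filter_tiles, qc_slide
from .slideio import read_slide


@dataclass(frozen=True)
class DeviceInput:
    wsi_path: str
    tissue_site: str
    disease_stage: str


@dataclass(frozen=True)
class TierThresholds:
    """Two operating thresholds: high-sensitivity (low_cut) below
    high-specificity (high_cut)."""

    low_cut: float
    high_cut: float

    def __post_init__(self):
        if not 0.0 <= self.low_cut < self.high_cut <= 1.0:
            raise ValueError("need 0 <= low_cut < high_cut <= 1")


@dataclass
class DeviceResult:
    status: str  # "ok" | "error"
    slide_id: str = ""
    error_message: str | None = None
    likelihood: float | None = None
    call: str | None = None  # "FGFR+" | "FGFR-"
    tier: str | None = None  # "Low" | "Mid" | "High"
    n_tiles_used: int = 0
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def check_metadata(inp: DeviceInput, strict: bool = False) -> None:
    """Gate on tissue site then disease stage.

    Default comparison trims whitespace and ignores case (deployment
    robustness); ``strict`` demands the literal strings "Bladder" and
    "MIBC".
    """

    def norm(s: str) -> str:
        return s if strict else s.strip().casefold()

    if norm(inp.tissue_site) != norm("Bladder"):
        raise MetadataError(MSG_TISSUE_SITE)
    if norm(inp.disease_stage) != norm("MIBC"):
        raise MetadataError(MSG_DISEASE_STAGE)


def binarize(likelihood: float, threshold: float) -> str:
    """FGFR+ iff likelihood >= threshold (boundary inclusive)."""
    return "FGFR+" if likelihood >= threshold else "FGFR-"


def assign_tier(likelihood: float, tiers: TierThresholds) -> str:
    """Low below low_cut, High at or above high_cut, Mid between."""
    if likelihood < tiers.low_cut:
        return "Low"
    if likelihood >= tiers.high_cut:
        return "High"
    return "Mid"


def run_device(
    inp: DeviceInput,
    model: MILModel,
    threshold: float | None = None,
    tiers: TierThresholds | None = None,
    backbone=None,
    qc_config=DEFAULT_QC_CONFIG,
    strict_metadata: bool = False,
    allow_resample: bool = False,
) -> DeviceResult:
    """Run the full device pipeline on one slide.

    Expected failures surface as the six contract error messages in the
    result; anything else propagates as an ordinary exception (internal
    error, distinct from the contract).
    """
    threshold = model.threshold if threshold is None else threshold
    backbone = backbone or HandcraftedBackbone()
    timings: dict[str, float] = {}
    result = DeviceResult(status="error", timings_s=timings)
    try:
        t0 = time.perf_counter()
        check_metadata(inp, strict=strict_metadata)
        timings["metadata"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        slide = read_slide(inp.wsi_path, allow_resample=allow_resample)
        result.slide_id = slide.slide_id
        timings["read"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        records = qc_slide(slide, qc_config)
        kept = filter_tiles(records, qc_config.score_threshold)
        timings["qc"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        tiles = [slide.region(r.tile.x, r.tile.y, r.tile.size, r.tile.size) for r in kept]
        bag = extract_features(tiles, backbone, tile_refs=[r.tile for r in kept])
        timings["features"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        pred = predict_slide(bag, model)
        timings["inference"] = time.perf_counter() - t0
    except DeviceError as exc:
        result.error_message = exc.message
        return result

    result.status = "ok"
    result.likelihood = pred.likelihood
    result.call = binarize(pred.likelihood, threshold)
    result.n_tiles_used = bag.n
    if tiers is not None:
        result.tier = assign_tier(pred.likelihood, tiers)
    return result


def run_batch(
    manifest: pd.DataFrame,
    model: MILModel,
    threshold: float | None = None,
    tiers: TierThresholds | None = None,
    backbone=None,
    qc_config=DEFAULT_QC_CONFIG,
) -> tuple[list[DeviceResult], pd.DataFrame]:
    """Process a manifest; returns per-slide results and a summary row.

    The summary mirrors deployment accounting: slides received, number
    with a prediction, number failing QC (or any other contract error).
    """
    backbone = backbone or HandcraftedBackbone()
    results = []
    for row in manifest.itertuples():
        inp = DeviceInput(
            wsi_path=row.file_path,
            tissue_site=getattr(row, "tissue_site", "Bladder"),
            disease_stage=getattr(row, "disease_stage", "MIBC"),
        )
        res = run_device(inp, model, threshold=threshold, tiers=tiers, backbone=backbone, qc_config=qc_config)
        if not res.slide_id:
            res.slide_id = row.slide_id
        results.append(res)
    n = len(results)
    n_ok = sum(r.status == "ok" for r in results)
    summary = pd.DataFrame(
        [
            {
                "received": n,
                "predicted": n_ok,
                "errored": n - n_ok,
                "prediction_rate_percent": 100.0 * n_ok / n if n else float("nan"),
            }
        ]
    )
    return results, summary
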