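"""Pre-screening decision rule and automated-vs-manual agreement analysis.

A biopsy image is flagged for further clinical attention when its class-2
(endomysial microvessel) percent area strictly exceeds an alert threshold,
4% by default — densities above that level are suggestive of an
immune-mediated necrotizing myopathy rather than polymyositis, whose
capillary density is typically reduced. :func:`run_protocol` chains the full
per-image pipeline (load → grayscale → brightness gate → probability map →
threshold filter → decision) with per-image fault isolation.

:func:`agreement` compares automated density readouts against matched
manual measurements by ordinary least squares (manual regressed on
automated), reporting slope, intercept, r², and the F test for a non-zero
slope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateRegressionError, MVQuantError
from .forest import PixelForestClassifier
from .image_io import DEFAULT_GATE_BOUNDS, brightness_gate, load_image, to_grayscale
from .quantify import DEFAULT_GRAY_BOUNDS, QuantResult, threshold_filter

__all__ = [
    "DEFAULT_ALERT_THRESHOLD",
    "ScreeningDecision",
    "ScreenConfig",
    "ProtocolReport",
    "decide",
    "agreement",
    "AgreementReport",
    "run_protocol",
]

logger = logging.getLogger(__name__)

#: Percent-area alert level: strictly above this, the image is flagged.
DEFAULT_ALERT_THRESHOLD = 4.0


@dataclass(frozen=True)
class ScreeningDecision:
    """Outcome of the density decision rule for one image."""

    image_id: str
    percent_area: float
    alert_threshold: float
    flagged: bool
    rationale: str


def decide(qr: QuantResult, alert_threshold: float = DEFAULT_ALERT_THRESHOLD) -> ScreeningDecision:
    """Flag when percent area strictly exceeds the alert threshold.

    The comparison is strict: exactly at the threshold is not flagged.
    The decision is pure — it reads only the quantification result.
    """
    flagged = qr.percent_area > alert_threshold
    rationale = (
        f"class-{qr.class_label} area {qr.percent_area:.3f}% "
        f"{'exceeds' if flagged else 'does not exceed'} alert threshold {alert_threshold:g}%"
    )
    return ScreeningDecision(
        image_id=qr.image_id,
        percent_area=qr.percent_area,
        alert_threshold=alert_threshold,
        flagged=flagged,
        rationale=rationale,
    )


@dataclass(frozen=True)
class AgreementReport:
    """OLS agreement between automated and manual density measurements."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float


def agreement(auto: Sequence[float], manual: Sequence[float]) -> AgreementReport:
    """Regress manual measurements on automated ones (simple OLS).

    Returns slope, intercept, r², and the F statistic (with its two-sided
    p-value from F(1, n-2)) testing slope != 0. Both regression directions
    give the same r².

    Raises
    ------
    DegenerateRegressionError
        For n < 3, non-finite values, or a constant predictor.
    """
    x = np.asarray(auto, dtype=np.float64)
    y = np.asarray(manual, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateRegressionError("auto and manual must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise DegenerateRegressionError(f"agreement requires n >= 3, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateRegressionError("agreement requires finite values")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("automated measurements are constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 0.0
    dof = n - 2
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = dof * r2 / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, dof))
    return AgreementReport(
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_statistic=float(f_stat),
        p_value=p,
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration for the screening protocol run."""

    class_label: int = 2
    gray_low: int = DEFAULT_GRAY_BOUNDS[0]
    gray_high: int = DEFAULT_GRAY_BOUNDS[1]
    alert_threshold: float = DEFAULT_ALERT_THRESHOLD
    gate_min: float = DEFAULT_GATE_BOUNDS[0]
    gate_max: float = DEFAULT_GATE_BOUNDS[1]
    gate_enabled: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ProtocolReport:
    """All per-image records plus summary counts for one screening batch."""

    records: tuple[dict, ...]
    n_flagged: int
    n_clear: int
    n_skipped: int
    n_errors: int
    config: ScreenConfig

    @property
    def exit_code(self) -> int:
        return 1 if self.n_errors else 0

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "flagged": self.n_flagged,
                    "clear": self.n_clear,
                    "skipped": self.n_skipped,
                    "errors": self.n_errors,
                }
            ]
        )


def _screen_one(path: Path, model: PixelForestClassifier, config: ScreenConfig) -> dict:
    raw = load_image(path)
    gray = to_grayscale(raw)
    record: dict = {
        "image": gray.source_id,
        "path": str(path),
        "mean_intensity": gray.mean_intensity,
    }
    if config.gate_enabled:
        verdict = brightness_gate(gray, config.gate_min, config.gate_max)
        record["gate"] = "pass" if verdict.passed else "fail"
        if not verdict.passed:
            record.update(status="skipped", reason=verdict.reason, flagged=False)
            return record
    else:
        record["gate"] = "disabled"
    pmap = model.predict_maps(gray)[config.class_label]
    qr = threshold_filter(pmap, config.gray_low, config.gray_high)
    decision = decide(qr, config.alert_threshold)
    record.update(
        status="flagged" if decision.flagged else "clear",
        flagged=decision.flagged,
        retained_count=qr.retained_count,
        total_count=qr.total_count,
        percent_area=qr.percent_area,
        alert_threshold=config.alert_threshold,
        gray_low=config.gray_low,
        gray_high=config.gray_high,
        rationale=decision.rationale,
    )
    return record


def run_protocol(
    paths: Sequence[str | Path],
    model: PixelForestClassifier,
    config: ScreenConfig = ScreenConfig(),
) -> ProtocolReport:
    """Run the screening pipeline over a batch of image files.

    Each image is processed independently; a failure on one image is
    recorded as an error record and the batch continues. Every record
    carries all intermediate numbers (mean intensity, retained/total pixel
    counts, percent area) for provenance.
    """
    records: list[dict] = []
    n_flagged = n_clear = n_skipped = n_errors = 0
    for p in paths:
        p = Path(p)
        try:
            rec = _screen_one(p, model, config)
        except MVQuantError as exc:
            logger.error("screening failed for %s: %s", p, exc)
            rec = {
                "image": p.stem,
                "path": str(p),
                "status": "error",
                "flagged": False,
                "reason": str(exc),
            }
        records.append(rec)
        status = rec["status"]
        if status == "flagged":
            n_flagged += 1
        elif status == "clear":
            n_clear += 1
        elif status == "skipped":
            n_skipped += 1
        else:
            n_errors += 1
    return ProtocolReport(
        records=tuple(records),
        n_flagged=n_flagged,
        n_clear=n_clear,
        n_skipped=n_skipped,
        n_errors=n_errors,
        config=config,
    )
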