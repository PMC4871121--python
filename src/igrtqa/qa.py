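"""Clinical-vs-verification discrepancy reporting.

The verification layer compares the couch correction applied clinically
with the one recovered by the independent registration, flags components
whose absolute difference exceeds configurable warning/error thresholds,
and aggregates per-case reports into batch statistics (mean differences,
exceedance fractions, maxima).  Report files are what a notification hook
would attach; dispatching notifications is outside this package.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, CouchCorrection

STATUS_OK = "OK"
STATUS_WARNING = "WARNING"
STATUS_ERROR = "ERROR"

#: Scheduler exit codes per status.
EXIT_CODES = {STATUS_OK: 0, STATUS_WARNING: 1, STATUS_ERROR: 2}


@dataclass(frozen=True)
class QAThresholds:
    """Per-component absolute-difference thresholds (mm / degrees)."""

    warn_translation: float = 2.0
    error_translation: float = 3.0
    warn_rotation: float = 1.0
    error_rotation: float = 1.5

    def __post_init__(self) -> None:
        if min(self.warn_translation, self.error_translation,
               self.warn_rotation, self.error_rotation) <= 0:
            raise ConfigError("QA thresholds must be positive")
        if self.warn_translation > self.error_translation:
            raise ConfigError("warn_translation must be <= error_translation")
        if self.warn_rotation > self.error_rotation:
            raise ConfigError("warn_rotation must be <= error_rotation")

    def limits_for(self, component: str) -> tuple[float, float]:
        if component in CouchCorrection.TRANSLATION_FIELDS:
            return self.warn_translation, self.error_translation
        return self.warn_rotation, self.error_rotation


@dataclass
class QAReport:
    """Componentwise comparison of clinical and verification corrections."""

    clinical: CouchCorrection
    verification: CouchCorrection
    differences: dict[str, float]
    status: str
    worst_component: str | None
    thresholds: QAThresholds
    verification_alt: CouchCorrection | None = None
    optimizer_disagreement: dict[str, float] | None = None
    config_fingerprint: str = ""
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    @property
    def exit_code(self) -> int:
        return EXIT_CODES[self.status]

    def to_dict(self) -> dict:
        d = {
            "clinical": self.clinical.to_dict(),
            "verification": self.verification.to_dict(),
            "differences": dict(self.differences),
            "status": self.status,
            "worst_component": self.worst_component,
            "thresholds": vars(self.thresholds).copy(),
            "config_fingerprint": self.config_fingerprint,
            "timestamp": self.timestamp,
        }
        if self.verification_alt is not None:
            d["verification_alt"] = self.verification_alt.to_dict()
        if self.optimizer_disagreement is not None:
            d["optimizer_disagreement"] = dict(self.optimizer_disagreement)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"Setup-verification report  [{self.status}]",
            f"  generated: {self.timestamp}",
            "  component   clinical   verified   diff",
        ]
        for name in (*CouchCorrection.TRANSLATION_FIELDS,
                     *CouchCorrection.ROTATION_FIELDS):
            unit = "mm" if name in CouchCorrection.TRANSLATION_FIELDS else "deg"
            lines.append(
                f"  {name:<10}{getattr(self.clinical, name):>9.2f} "
                f"{getattr(self.verification, name):>10.2f} "
                f"{self.differences[name]:>6.2f} {unit}"
            )
        if self.worst_component:
            lines.append(f"  worst offender: {self.worst_component}")
        if self.optimizer_disagreement:
            worst = max(self.optimizer_disagreement.items(), key=lambda kv: abs(kv[1]))
            lines.append(
                f"  optimizer cross-check: largest disagreement "
                f"{worst[1]:.2f} on {worst[0]}"
            )
        return "\n".join(lines)


def compare(
    clinical: CouchCorrection,
    verification: CouchCorrection,
    thresholds: QAThresholds | None = None,
    verification_alt: CouchCorrection | None = None,
    config_fingerprint: str = "",
) -> QAReport:
    """Compare corrections componentwise and assign OK/WARNING/ERROR.

    Status is ERROR iff any absolute difference exceeds its error
    threshold, WARNING iff (not ERROR and) any exceeds its warning
    threshold.  When a second verification solution (the other optimizer)
    is supplied, their mutual differences are recorded as the optimizer
    disagreement diagnostic; status is always judged on the primary.
    """
    thresholds = thresholds or QAThresholds()
    diff = clinical - verification
    differences = diff.to_dict()
    status = STATUS_OK
    worst: str | None = None
    worst_ratio = 0.0
    for name, value in differences.items():
        warn, error = thresholds.limits_for(name)
        ratio = abs(value) / error
        if ratio > worst_ratio:
            worst_ratio, worst = ratio, name
        if abs(value) > error:
            status = STATUS_ERROR
        elif abs(value) > warn and status != STATUS_ERROR:
            status = STATUS_WARNING
    disagreement = None
    if verification_alt is not None:
        disagreement = (verification - verification_alt).to_dict()
    return QAReport(
        clinical=clinical,
        verification=verification,
        differences=differences,
        status=status,
        worst_component=worst if worst_ratio > 0 else None,
        thresholds=thresholds,
        verification_alt=verification_alt,
        optimizer_disagreement=disagreement,
        config_fingerprint=config_fingerprint,
    )


@dataclass
class BatchSummary:
    """Aggregate statistics over a list of QA reports."""

    n: int
    mean_differences: dict[str, float]
    max_differences: dict[str, float]
    fraction_translation_gt: float
    fraction_rotation_gt: float
    translation_cutoff: float
    rotation_cutoff: float
    n_ok: int
    n_warning: int
    n_error: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def summarize_batch(
    reports: list[QAReport],
    translation_cutoff: float = 3.0,
    rotation_cutoff: float = 1.0,
) -> BatchSummary:
    """Exact batch statistics over per-case reports.

    ``fraction_translation_gt`` is the fraction of cases where any
    translational |difference| exceeds ``translation_cutoff`` (mm);
    analogously for rotations.  Means are signed; maxima are the
    largest-magnitude signed differences per component.
    """
    if not reports:
        raise ValueError("summarize_batch needs at least one report")
    comps = (*CouchCorrection.TRANSLATION_FIELDS, *CouchCorrection.ROTATION_FIELDS)
    arr = {c: np.array([r.differences[c] for r in reports]) for c in comps}
    mean = {c: float(arr[c].mean()) for c in comps}
    maxima = {c: float(arr[c][np.argmax(np.abs(arr[c]))]) for c in comps}
    t_mat = np.stack([np.abs(arr[c]) for c in CouchCorrection.TRANSLATION_FIELDS])
    r_mat = np.stack([np.abs(arr[c]) for c in CouchCorrection.ROTATION_FIELDS])
    frac_t = float(np.mean(np.any(t_mat > translation_cutoff, axis=0)))
    frac_r = float(np.mean(np.any(r_mat > rotation_cutoff, axis=0)))
    statuses = [r.status for r in reports]
    return BatchSummary(
        n=len(reports),
        mean_differences=mean,
        max_differences=maxima,
        fraction_translation_gt=frac_t,
        fraction_rotation_gt=frac_r,
        translation_cutoff=translation_cutoff,
        rotation_cutoff=rotation_cutoff,
        n_ok=statuses.count(STATUS_OK),
        n_warning=statuses.count(STATUS_WARNING),
        n_error=statuses.count(STATUS_ERROR),
    )


def plot_batch_differences(reports: list[QAReport], path, bins: int = 20) -> None:
    """Histogram the componentwise clinical-vs-verification differences."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = (*CouchCorrection.TRANSLATION_FIELDS, *CouchCorrection.ROTATION_FIELDS)
    fig, axes = plt.subplots(1, len(comps), figsize=(3 * len(comps), 2.8))
    for ax, comp in zip(np.atleast_1d(axes), comps):
        values = [r.differences[comp] for r in reports]
        unit = "mm" if comp in CouchCorrection.TRANSLATION_FIELDS else "deg"
        ax.hist(values, bins=bins, color="steelblue", edgecolor="k")
        ax.set_title(comp)
        ax.set_xlabel(unit)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
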