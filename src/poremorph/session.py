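"""Multi-pass analysis sessions.

One *pass* is a full run of the pipeline (preprocess -> trace ->
filter -> measure) over the loaded image with one settings bundle.  A
single settings bundle rarely outlines every pore well, so the
workflow is iterative: run a pass, save the contours that look right
(each saved pore permanently carries its pass's settings as its *save
profile*), re-run with different settings, and repeat.  Saved pores
persist across passes; detected-but-unsaved pores are replaced on the
next pass.

Pore numbering restarts at 1 each pass (matching the numeric labels
drawn on the overlay); the (pass_id, pore_id) pair is globally unique
and is what exports key on.

A session can be driven from a plain-text replay script for
reproducible curation::

    analyze grayscale_threshold=120 min_pore_size_px=200
    save 3
    saverange 5 9
    remove 4
    analyze grayscale_threshold=90
    save 1

Replaying the same script on the same image yields byte-identical
exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import Contour, DetectionResult, filter_contours, trace_contours
from .errors import ContractError, NotFoundError
from .measurement import PoreMeasurements, measure_pore
from .preprocessing import preprocess
from .scale import AnalysisSettings

__all__ = ["PoreRecord", "PassInfo", "Session", "run_script"]

#: how the pipeline measures pore area: enclosed-pixel count tracks the
#: physical region (the boundary polygon alone under-measures by about
#: half the perimeter).
PIPELINE_AREA_MODE = "pixel"


@dataclass
class PoreRecord:
    """One pore's contour, measurements and lifecycle state."""

    pore_id: int
    pass_id: int
    status: str  # detected | saved | removed_size | removed_hierarchy | removed_user
    contour: Contour
    measurements: PoreMeasurements | None
    save_profile: AnalysisSettings


@dataclass
class PassInfo:
    """Bookkeeping for one analysis pass."""

    pass_id: int
    settings: AnalysisSettings
    detection: DetectionResult
    stages: dict[str, np.ndarray]  # original / clahe / denoised / threshold
    n_accepted_at_detection: int
    removed_user: list[PoreRecord] = field(default_factory=list)


class Session:
    """Analysis state for one image across any number of passes."""

    def __init__(self, image: np.ndarray):
        image = np.asarray(image)
        if image.ndim != 2 or image.size == 0:
            raise ContractError(f"expected a 2-D grayscale image, got shape {image.shape}")
        self.image = image.astype(np.uint8)
        self.passes: list[PassInfo] = []
        self.saved: list[PoreRecord] = []
        self.current_detected: list[PoreRecord] = []

    # -- passes ---------------------------------------------------------

    @property
    def last_pass(self) -> PassInfo | None:
        return self.passes[-1] if self.passes else None

    def run_pass(self, settings: AnalysisSettings) -> "Session":
        """Run one full analysis pass; replaces the detected set.

        Saved pores are untouched.  An empty accepted set is a valid
        outcome, not an error.
        """
        stages = preprocess(self.image, settings)
        binary = stages["threshold"]
        traced = trace_contours(binary)
        detection = filter_contours(
            traced,
            settings.min_pore_size_px,
            settings.max_pore_size_px,
            image_dims=binary.shape,
            settings=settings,
        )
        pass_id = (self.passes[-1].pass_id + 1) if self.passes else 1
        detected: list[PoreRecord] = []
        for i, c in enumerate(detection.accepted, start=1):
            m = measure_pore(c, binary, settings.scale, area_mode=PIPELINE_AREA_MODE)
            detected.append(
                PoreRecord(
                    pore_id=i,
                    pass_id=pass_id,
                    status="detected",
                    contour=c,
                    measurements=m,
                    save_profile=settings,
                )
            )
        self.passes.append(
            PassInfo(
                pass_id=pass_id,
                settings=settings,
                detection=detection,
                stages=stages,
                n_accepted_at_detection=len(detected),
            )
        )
        self.current_detected = detected
        return self

    # -- curation -------------------------------------------------------

    def _pop_detected(self, pore_id: int) -> PoreRecord:
        for i, rec in enumerate(self.current_detected):
            if rec.pore_id == pore_id:
                return self.current_detected.pop(i)
        raise NotFoundError(f"pore id {pore_id} is not in the detected set")

    def save_contour(self, pore_id: int) -> "Session":
        """Move a detected pore into the persistent saved list."""
        rec = self._pop_detected(pore_id)
        rec.status = "saved"
        self.saved.append(rec)
        return self

    def remove_contour(self, pore_id: int) -> "Session":
        """Discard a detected pore (user rejection)."""
        rec = self._pop_detected(pore_id)
        rec.status = "removed_user"
        self.passes[-1].removed_user.append(rec)
        return self

    def _range_ids(self, id_lo: int, id_hi: int) -> list[int]:
        if id_lo > id_hi:
            raise ContractError(f"empty range: {id_lo} > {id_hi}")
        detected = {rec.pore_id for rec in self.current_detected}
        return [i for i in range(id_lo, id_hi + 1) if i in detected]

    def save_range(self, id_lo: int, id_hi: int) -> "Session":
        """Save every currently-detected id in [id_lo, id_hi]; absent ids are skipped."""
        for i in self._range_ids(id_lo, id_hi):
            self.save_contour(i)
        return self

    def remove_range(self, id_lo: int, id_hi: int) -> "Session":
        """Remove every currently-detected id in [id_lo, id_hi]; absent ids are skipped."""
        for i in self._range_ids(id_lo, id_hi):
            self.remove_contour(i)
        return self


# -- replay scripts -----------------------------------------------------


def run_script(
    session: Session,
    text: str,
    base_settings: AnalysisSettings,
) -> Session:
    """Drive a session from a plain-text command script.

    Commands (one per line; blank lines and ``#`` comments ignored):

    - ``analyze [key=value ...]`` — run a pass; keys override fields of
      ``base_settings`` for that pass only
    - ``save N`` / ``remove N``
    - ``saverange A B`` / ``removerange A B``

    A malformed command or an unknown pore id aborts with the line
    number in the error message.
    """
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        cmd, args = parts[0].lower(), parts[1:]
        try:
            if cmd == "analyze":
                overrides = {}
                for a in args:
                    if "=" not in a:
                        raise ContractError(f"expected key=value, got {a!r}")
                    k, v = a.split("=", 1)
                    overrides[k] = v
                settings = base_settings
                if overrides:
                    from .scale import _SETTING_KEYS

                    for k in overrides:
                        if k not in _SETTING_KEYS:
                            raise ContractError(f"unknown analysis setting {k!r}")
                    typed = {k: _SETTING_KEYS[k](v) for k, v in overrides.items()}
                    settings = base_settings.replace(**typed)
                session.run_pass(settings)
            elif cmd in ("save", "remove"):
                (pid,) = (int(a) for a in args)
                (session.save_contour if cmd == "save" else session.remove_contour)(pid)
            elif cmd in ("saverange", "removerange"):
                lo, hi = (int(a) for a in args)
                (session.save_range if cmd == "saverange" else session.remove_range)(lo, hi)
            else:
                raise ContractError(f"unknown command {cmd!r}")
        except (ContractError, NotFoundError, TypeError, ValueError) as exc:
            raise ContractError(f"replay script line {lineno}: {exc}") from exc
    return session
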