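"""Temporal alignment of paired angle traces.

Two systems watch the same movement at different rates and with manually
operated start/stop, so traces cannot be compared sample by sample.  The
pairing procedure automated here:

1. **Section extraction** — locate the global maximum and minimum of a
   representative indicator trace and cut the span between them (whichever
   comes first); the same normalized window applies to every indicator of
   the trial.
2. **Time normalization** — linearly resample the cut section of each
   system onto a common grid of ``n`` frames (100 by default), i.e. onto
   normalized movement time [0, 1].
3. **Sign harmonization** — if the two systems encode the signed trunk
   side-bend with opposite conventions, negate and retag the reference.

The result is an :class:`AlignedTracePair`, the unit on which all
agreement statistics operate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, NoMotionError, TaskMismatchError
from .series import AngleTrace, SignConvention

__all__ = [
    "SectionWindow",
    "AlignedTracePair",
    "extract_section",
    "apply_window",
    "resample_to_n",
    "harmonize_signs",
    "pair_traces",
]

log = logging.getLogger(__name__)

N_FRAMES_DEFAULT = 100


@dataclass(frozen=True)
class SectionWindow:
    """Frame span between the representative indicator's two global extrema."""

    start: int
    end: int
    representative: str
    vmax: float
    vmin: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AlignmentError(f"invalid window [{self.start}, {self.end}]")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass
class AlignedTracePair:
    """Test and reference traces on a shared normalized 100-frame grid."""

    test: np.ndarray
    reference: np.ndarray
    t_norm: np.ndarray
    convention: SignConvention
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.test = np.asarray(self.test, float)
        self.reference = np.asarray(self.reference, float)
        self.t_norm = np.asarray(self.t_norm, float)
        if not (self.test.shape == self.reference.shape == self.t_norm.shape):
            raise AlignmentError("test, reference and grid must have equal length")
        self.convention = SignConvention(self.convention)

    @property
    def n_frames(self) -> int:
        return self.test.size

    def as_table(self) -> np.ndarray:
        """(n, 2) ratings table: frames as subjects, systems as raters."""
        return np.column_stack([self.test, self.reference])


def extract_section(
    trace: AngleTrace, representative: AngleTrace | None = None
) -> SectionWindow:
    """Window of ``trace`` spanned by the representative's global extrema.

    ``representative`` defaults to the trace itself (single-indicator
    trials).  Ties are broken by the earliest index; a constant
    representative has no extrema and raises :class:`NoMotionError`.
    """
    rep = representative if representative is not None else trace
    if len(rep) < 2:
        raise AlignmentError("representative trace must have at least 2 samples")
    vals = rep.values
    if not np.isfinite(vals).any():
        raise AlignmentError("representative trace is all-missing")
    imax = int(np.nanargmax(vals))
    imin = int(np.nanargmin(vals))
    vmax, vmin = float(vals[imax]), float(vals[imin])
    if vmax == vmin:
        raise NoMotionError("representative trace is constant; no max/min section")
    start, end = sorted((imax, imin))
    name = str(rep.meta.get("name", rep.task.value if rep.task else "representative"))
    return SectionWindow(start=start, end=end, representative=name, vmax=vmax, vmin=vmin)


def apply_window(trace: AngleTrace, window: SectionWindow, rep_length: int | None = None) -> AngleTrace:
    """Cut a trace to a section window defined on a representative.

    When the representative lived on a different grid, ``rep_length`` maps
    the window into normalized time first.
    """
    if rep_length is None or rep_length == len(trace):
        lo, hi = window.start, window.end
    else:
        frac_lo = window.start / (rep_length - 1)
        frac_hi = window.end / (rep_length - 1)
        lo = int(round(frac_lo * (len(trace) - 1)))
        hi = int(round(frac_hi * (len(trace) - 1)))
    if hi - lo < 1:
        raise AlignmentError("section window collapses to fewer than 2 samples")
    return trace.with_values(trace.values[lo : hi + 1])


def resample_to_n(trace: AngleTrace, n: int = N_FRAMES_DEFAULT) -> AngleTrace:
    """Linearly resample a trace onto ``n`` evenly spaced normalized times.

    The first and last samples are preserved exactly; resampling a trace
    onto its own length reproduces it bit for bit.  Interior missing
    samples are bridged linearly (with a warning); an all-missing trace is
    an error.
    """
    if n < 2:
        raise AlignmentError("n must be >= 2")
    if len(trace) < 2:
        raise AlignmentError("trace must have at least 2 samples to resample")
    vals = trace.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise AlignmentError("cannot resample an all-missing trace")
    if not finite.all():
        if not (finite[0] and finite[-1]):
            raise AlignmentError("trace endpoints are missing; section is not bridgeable")
        log.warning(
            "bridging %d interior missing sample(s) by linear interpolation",
            int((~finite).sum()),
        )
        idx = np.arange(vals.size)
        vals = np.interp(idx, idx[finite], vals[finite])
    x = np.linspace(0.0, 1.0, vals.size)
    xi = np.linspace(0.0, 1.0, n)
    out = np.interp(xi, x, vals)
    duration = (len(trace) - 1) / trace.rate_hz
    out_rate = (n - 1) / duration if duration > 0 else trace.rate_hz
    resampled = trace.with_values(out, rate_hz=out_rate)
    resampled.meta["resampled_from_n"] = len(trace)
    return resampled


def harmonize_signs(test: AngleTrace, reference: AngleTrace) -> tuple[AngleTrace, AngleTrace]:
    """Bring two paired traces onto the test trace's sign convention.

    A reference exported right-positive is negated and retagged to
    left-positive.  Mixing a signed with an unsigned trace, or two
    different task families, is a pairing error.
    """
    if test.task is not None and reference.task is not None:
        if test.task.family != reference.task.family:
            raise TaskMismatchError(
                f"cannot pair task {test.task.value} with {reference.task.value}"
            )
    if test.convention.is_signed != reference.convention.is_signed:
        raise TaskMismatchError(
            f"sign conventions are incompatible: {test.convention.value} vs "
            f"{reference.convention.value}"
        )
    if reference.convention is test.convention:
        return test, reference
    # both signed, opposite handedness: flip the reference
    return test, reference.negated(convention=test.convention)


def pair_traces(
    test: AngleTrace,
    reference: AngleTrace,
    provenance: dict | None = None,
    n: int = N_FRAMES_DEFAULT,
    representative: str = "reference",
) -> AlignedTracePair:
    """Full pairing procedure: section, resample to ``n``, harmonize signs.

    One representative indicator defines the max–min section for the whole
    trial, and that window — mapped through normalized time — is applied to
    both traces.  ``representative`` selects it: ``"reference"`` (default;
    the designated gold-standard trace), ``"test"``, or ``"each"`` in which
    case every trace is cut on its own extrema.  The shared-representative
    default matters when a movement returns to its start value: the global
    minimum of a noisy trace then falls at either end at random, and
    per-trace windows can select the rising half of one system but the
    falling half of the other.
    """
    if representative not in ("reference", "test", "each"):
        raise AlignmentError(f"unknown representative mode {representative!r}")
    test, reference = harmonize_signs(test, reference)
    if representative == "each":
        w_test = extract_section(test)
        w_ref = extract_section(reference)
        test_cut = apply_window(test, w_test)
        ref_cut = apply_window(reference, w_ref)
    else:
        rep_trace = reference if representative == "reference" else test
        w_ref = w_test = extract_section(rep_trace)
        test_cut = apply_window(test, w_test, rep_length=len(rep_trace))
        ref_cut = apply_window(reference, w_ref, rep_length=len(rep_trace))
    test_n = resample_to_n(test_cut, n)
    ref_n = resample_to_n(ref_cut, n)
    prov = dict(provenance or {})
    prov.setdefault("source_rates_hz", (test.rate_hz, reference.rate_hz))
    prov.setdefault("windows", {"test": (w_test.start, w_test.end), "reference": (w_ref.start, w_ref.end)})
    log.info(
        "paired traces: test window [%d, %d] of %d, reference window [%d, %d] of %d -> %d frames",
        w_test.start, w_test.end, len(test), w_ref.start, w_ref.end, len(reference), n,
    )
    return AlignedTracePair(
        test=test_n.values,
        reference=ref_n.values,
        t_norm=np.linspace(0.0, 1.0, n),
        convention=test.convention,
        provenance=prov,
    )
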