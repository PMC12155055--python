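"""Spectral preprocessing operators and labelled chains.

Seven operators are provided — Savitzky-Golay smoothing (SG), min-max or
vector normalization (Normalize), multiplicative scatter correction (MSC),
standard normal variate (SNV), first and second derivatives (1Der, 2Der,
Savitzky-Golay based), and linear baseline removal (Baseline) — plus chains
of operators written as "+"-joined labels applied left to right, e.g.
"1Der+SNV" differentiates first and standardizes second.

Conventions fixed here so results are exactly reproducible:

* SNV divides by the sample standard deviation (n - 1 denominator).
* MSC regresses each spectrum on a reference (default: the column-wise mean
  of the input) and inverts the fitted affine distortion.
* Derivatives are scaled by the wavelength step, so 1Der is d A / d lambda
  in absorbance per nm, and the wavelength axis is cropped by half a window
  on each side rather than padded.
* "Original" (or the empty string) is the identity chain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraMatrix

__all__ = [
    "snv",
    "msc",
    "savitzky_golay",
    "normalize",
    "baseline_correct",
    "PreprocessChain",
    "parse_chain",
    "apply_chain",
]

SG_DEFAULT_WINDOW = 15
SG_DEFAULT_POLYORDER = 2


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: center and scale each spectrum.

    Each row becomes (x - mean(x)) / sd(x) with the sample (n - 1) standard
    deviation, removing per-spectrum additive offsets and multiplicative
    scaling without any reference spectrum.
    """
    x = spectra.absorbance
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"SNV undefined for constant spectra: sample(s) "
            f"{spectra.sample_ids[bad].tolist()}"
        )
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra.with_absorbance(out)


def msc(
    spectra: SpectraMatrix,
    reference: np.ndarray | None = None,
    slope_tol: float = 1e-12,
) -> SpectraMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Fits x ~ a + b * reference per row by least squares and returns
    (x - a) / b.  The default reference is the column-wise mean of the
    input, so correcting a calibration set and then a prediction set should
    pass the calibration reference explicitly.  The reference used is
    attached to the result as ``msc_reference``.
    """
    x = spectra.absorbance
    if reference is None:
        if spectra.n_samples < 2:
            raise ValueError("MSC needs >= 2 spectra when no reference is given")
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.size != spectra.n_wavelengths:
        raise ValueError("reference length does not match wavelength axis")

    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    xc = x - x.mean(axis=1, keepdims=True)
    b = xc @ ref_c / denom
    small = np.flatnonzero(np.abs(b) < slope_tol)
    if small.size:
        raise ValueError(
            f"MSC slope below tolerance (spectrum orthogonal to reference) for "
            f"sample(s) {spectra.sample_ids[small].tolist()}"
        )
    a = x.mean(axis=1) - b * reference.mean()
    out = (x - a[:, None]) / b[:, None]
    result = spectra.with_absorbance(out)
    result.msc_reference = reference
    return result


def savitzky_golay(
    spectra: SpectraMatrix,
    window_points: int = SG_DEFAULT_WINDOW,
    polyorder: int = SG_DEFAULT_POLYORDER,
    deriv_order: int = 0,
) -> SpectraMatrix:
    """Savitzky-Golay smoothing or derivative.

    deriv_order 0 is plain smoothing; 1 and 2 are the first and second
    derivatives with respect to wavelength (scaled by the nm step).  For
    derivatives the axis is cropped by ``window_points // 2`` on each side
    so no extrapolated edge values enter downstream modeling.
    """
    if window_points % 2 == 0 or window_points < 1:
        raise ValueError("window_points must be odd and positive")
    if window_points <= polyorder:
        raise ValueError("window_points must exceed polyorder")
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1 or 2")
    if deriv_order > polyorder:
        raise ValueError("deriv_order must not exceed polyorder")
    if window_points > spectra.n_wavelengths:
        raise ValueError(
            f"window of {window_points} points exceeds spectrum length "
            f"{spectra.n_wavelengths}"
        )
    steps = np.diff(spectra.wavelengths_nm)
    delta = float(steps[0])
    if not np.allclose(steps, delta):
        raise ValueError("Savitzky-Golay requires an evenly spaced axis")
    out = savgol_filter(
        spectra.absorbance,
        window_length=window_points,
        polyorder=polyorder,
        deriv=deriv_order,
        delta=delta,
        axis=1,
        mode="interp",
    )
    if deriv_order == 0:
        return spectra.with_absorbance(out)
    half = window_points // 2
    sl = slice(half, spectra.n_wavelengths - half)
    return spectra.with_absorbance(out[:, sl], spectra.wavelengths_nm[sl])


def normalize(spectra: SpectraMatrix, method: str = "minmax") -> SpectraMatrix:
    """Per-spectrum intensity normalization.

    ``minmax`` maps each row onto [0, 1]; ``vector`` divides each row by its
    Euclidean norm.
    """
    x = spectra.absorbance
    if method == "minmax":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        span = hi - lo
        bad = np.flatnonzero(span.ravel() == 0)
        if bad.size:
            raise ValueError(
                f"min-max normalization undefined for constant spectra: "
                f"sample(s) {spectra.sample_ids[bad].tolist()}"
            )
        out = (x - lo) / span
    elif method == "vector":
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        bad = np.flatnonzero(norm.ravel() == 0)
        if bad.size:
            raise ValueError(
                f"vector normalization undefined for all-zero spectra: "
                f"sample(s) {spectra.sample_ids[bad].tolist()}"
            )
        out = x / norm
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return spectra.with_absorbance(out)


def baseline_correct(spectra: SpectraMatrix) -> SpectraMatrix:
    """Remove each spectrum's least-squares straight line (linear detrend)."""
    if spectra.n_wavelengths < 3:
        raise ValueError("baseline correction needs >= 3 points per spectrum")
    wl = spectra.wavelengths_nm
    design = np.column_stack([np.ones_like(wl), wl])
    coef, *_ = np.linalg.lstsq(design, spectra.absorbance.T, rcond=None)
    out = spectra.absorbance - (design @ coef).T
    return spectra.with_absorbance(out)


@dataclass(frozen=True)
class ChainStep:
    name: str
    params: tuple[tuple[str, float], ...] = ()

    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class PreprocessChain:
    """Ordered list of operators with a canonical "+"-joined label."""

    steps: tuple[ChainStep, ...]

    @property
    def label(self) -> str:
        if not self.steps:
            return "Original"
        parts = []
        for step in self.steps:
            if step.params:
                inner = ",".join(f"{k}={_fmt(v)}" for k, v in step.params)
                parts.append(f"{step.name}({inner})")
            else:
                parts.append(step.name)
        return "+".join(parts)

    def __len__(self) -> int:
        return len(self.steps)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


_STEP_RE = re.compile(r"^(?P<name>[A-Za-z0-9]+)(?:\((?P<params>[^()]*)\))?$")
_KNOWN = {"SG", "Normalize", "MSC", "SNV", "1Der", "2Der", "Baseline"}
# the paper's tables hyphenate derivative labels ("1-Der"); accept both
_ALIASES = {"1-Der": "1Der", "2-Der": "2Der", "original": "Original"}


def parse_chain(label: str) -> PreprocessChain:
    """Parse a chain label like "SG(window=15,poly=2)+SNV" into steps."""
    label = label.strip()
    if label in ("", "Original", "original"):
        return PreprocessChain(())
    steps = []
    for part in label.split("+"):
        part = part.strip()
        part = _ALIASES.get(part, part)
        m = _STEP_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse chain step {part!r}")
        name = _ALIASES.get(m.group("name"), m.group("name"))
        if name not in _KNOWN:
            raise ValueError(f"unknown preprocessing operator {name!r}")
        params = ()
        if m.group("params"):
            kv = []
            for item in m.group("params").split(","):
                key, _, val = item.partition("=")
                if not val:
                    raise ValueError(f"malformed parameter {item!r} in {part!r}")
                kv.append((key.strip(), float(val)))
            params = tuple(kv)
        steps.append(ChainStep(name, params))
    return PreprocessChain(tuple(steps))


def _apply_step(
    step: ChainStep, spectra: SpectraMatrix, msc_reference: np.ndarray | None
) -> SpectraMatrix:
    p = step.param_dict()
    if step.name == "SNV":
        return snv(spectra)
    if step.name == "MSC":
        return msc(spectra, reference=msc_reference)
    if step.name == "SG":
        return savitzky_golay(
            spectra,
            window_points=int(p.get("window", SG_DEFAULT_WINDOW)),
            polyorder=int(p.get("poly", SG_DEFAULT_POLYORDER)),
            deriv_order=0,
        )
    if step.name in ("1Der", "2Der"):
        order = 1 if step.name == "1Der" else 2
        return savitzky_golay(
            spectra,
            window_points=int(p.get("window", SG_DEFAULT_WINDOW)),
            polyorder=int(p.get("poly", SG_DEFAULT_POLYORDER)),
            deriv_order=order,
        )
    if step.name == "Normalize":
        method = p.get("method", "minmax")
        if isinstance(method, float):  # numeric parse artifact
            raise ValueError("Normalize method must be 'minmax' or 'vector'")
        return normalize(spectra, method=method)
    if step.name == "Baseline":
        return baseline_correct(spectra)
    raise ValueError(f"unknown operator {step.name!r}")


def apply_chain(
    chain: PreprocessChain | str,
    spectra: SpectraMatrix,
    msc_references: list[np.ndarray] | None = None,
) -> SpectraMatrix:
    """Apply a chain left to right; "1Der+SNV" derives first, then SNV.

    ``msc_references`` optionally supplies one reference spectrum per MSC
    step (in chain order), so a chain fitted on a calibration set can be
    replayed on new spectra.  References actually used are recorded on the
    result as ``msc_references_used``.
    """
    if isinstance(chain, str):
        chain = parse_chain(chain)
    out = spectra
    refs_used: list[np.ndarray] = []
    msc_seen = 0
    for i, step in enumerate(chain.steps):
        ref = None
        if step.name == "MSC" and msc_references is not None:
            ref = msc_references[msc_seen]
        try:
            out = _apply_step(step, out, ref)
        except ValueError as err:
            raise ValueError(f"chain step {i} ({step.name}): {err}") from err
        if step.name == "MSC":
            refs_used.append(out.msc_reference)
            msc_seen += 1
    if out is spectra:
        out = spectra.copy()
    out.chain_label = chain.label
    out.msc_references_used = refs_used
    return out
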