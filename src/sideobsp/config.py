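"""Centralized numerical tolerances and solver knobs.

Every tolerance used anywhere in the package lives here so that a run
manifest can record the complete numerical configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class ToleranceConfig:
    """Numerical tolerances shared across the projector and solver layers.

    Attributes
    ----------
    projector_tol : float
        Tolerance for projector identities (idempotence, annihilation),
        relative to the matrix norm.
    pinv_rtol : float | None
        Relative singular-value cutoff for pseudoinverses. ``None`` means
        the conventional ``max(dim) * eps * sigma_max``.
    implicit_threshold : int
        Row count above which complement projectors are applied implicitly
        (via least-squares residuals against the reference block) instead of
        materializing the (N-p) x (N-p) matrix Q.
    cv_tie_rtol : float
        Relative band within which cross-validation errors are considered
        tied; ties break toward smaller gamma, then smaller order.
    tail_mass_fraction : float
        Fraction of trailing taps inspected by the impulse-response decay
        diagnostic (reported, never used for automatic order selection).
    """

    projector_tol: float = 1e-8
    pinv_rtol: float | None = None
    implicit_threshold: int = 2000
    cv_tie_rtol: float = 1e-12
    tail_mass_fraction: float = 0.1

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_TOLERANCES = ToleranceConfig()
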