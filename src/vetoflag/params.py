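"""Model parameter record.

All quantities that enter the simulations live in one validated,
YAML-round-trippable record.  Defaults are the wild-type *E. coli*
chemotaxis values used throughout: motor switching rates for a mean
clockwise bias of 0.13, the Hill map from CheY-P concentration to
instantaneous CW bias, and the fluctuation parameters of the
Ornstein-Uhlenbeck CheY-P process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class ParameterError(ValueError):
    """Raised when a parameter value is outside its physical domain."""


@dataclass
class HillParams:
    """Sigmoidal map from CheY-P concentration to instantaneous CW bias.

    ``cb = y**h / (kd**h + y**h)``

    Attributes
    ----------
    kd : float
        Midpoint concentration of the CW-bias response curve, µM.
    h : float
        Hill coefficient (dimensionless). The response is very steep
        (h ≈ 10), which is what lets modest concentration fluctuations
        drive near-all-or-none switching.
    """

    kd: float = 3.1
    h: float = 10.3

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ParameterError(f"kd must be > 0, got {self.kd}")
        if self.h <= 0:
            raise ParameterError(f"h must be > 0, got {self.h}")


@dataclass
class FluctuationParams:
    """Ornstein-Uhlenbeck CheY-P fluctuation parameters.

    The concentration Y(t) relaxes toward ``y_mean`` with timescale
    ``tau`` and is driven by Gaussian noise of amplitude set by
    ``sigma2``.  ``noise_mode`` selects the per-step amplitude:

    - ``"variance_matched"`` (default): amplitude sqrt(2 σ² dt/τ), so the
      stationary variance of Y equals σ² — the quantity the model table
      calls "variance in [CheY-P]".
    - ``"verbatim"``: amplitude sqrt(σ² dt/τ) as the update rule is
      printed, which realizes stationary variance σ²/2.
    """

    y_mean: float = 2.59
    sigma2: float = 1.0
    tau: float = 5.0
    dt: float = 0.001
    noise_mode: str = "variance_matched"

    def __post_init__(self) -> None:
        if self.y_mean <= 0:
            raise ParameterError(f"y_mean must be > 0, got {self.y_mean}")
        if self.sigma2 < 0:
            raise ParameterError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if not (0 < self.dt < self.tau):
            raise ParameterError(
                f"dt must satisfy 0 < dt < tau, got dt={self.dt}, tau={self.tau}"
            )
        if self.noise_mode not in ("verbatim", "variance_matched"):
            raise ParameterError(f"unknown noise_mode {self.noise_mode!r}")

    @property
    def step_amplitude(self) -> float:
        """Per-step noise amplitude A in the recursion Y += ... + A·ξ."""
        base = self.sigma2 * self.dt / self.tau
        if self.noise_mode == "variance_matched":
            base *= 2.0
        return base ** 0.5

    @property
    def stationary_variance(self) -> float:
        """Variance of Y under the discrete recursion (to O(dt/τ))."""
        return self.sigma2 if self.noise_mode == "variance_matched" else self.sigma2 / 2.0


@dataclass
class MotorParams:
    """Two-state (CCW/CW) flagellar motor switching.

    The motor is a telegraph process whose rates are set by the
    instantaneous CW bias ``cb`` and the characteristic switching
    time ``omega``:

        k_CCW→CW = cb / omega,     k_CW→CCW = (1 - cb) / omega

    so the stationary CW occupancy equals ``cb`` and the total
    relaxation rate is 1/omega independent of bias.
    """

    omega: float = 0.5

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ParameterError(f"omega must be > 0, got {self.omega}")

    def k_ccw_cw(self, cb: float) -> float:
        return cb / self.omega

    def k_cw_ccw(self, cb: float) -> float:
        return (1.0 - cb) / self.omega


@dataclass
class WaveformParams:
    """Three-state filament waveform overlay and run-rule variants.

    CCW rotation always shows the *normal* waveform.  On a CCW→CW
    switch the filament enters *semi-coiled* or *curly-1* with
    probabilities proportional to the normal-exit rates
    (``entry_rate_semi``, ``entry_rate_curly``); a semi-coiled filament
    converts irreversibly to curly-1 at rate ``lambda_rate`` within the
    CW interval.

    ``x_rule`` and ``curly_run_prob`` parameterize the run-rule
    variants (see ``flagella_sim.apply_run_rule``); the plain veto rule
    ignores both.
    """

    lambda_rate: float = 0.68
    entry_rate_semi: float = 0.28
    entry_rate_curly: float = 0.08
    x_rule: Optional[int] = None
    curly_run_prob: float = 0.18

    def __post_init__(self) -> None:
        for name in ("lambda_rate", "entry_rate_semi", "entry_rate_curly"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.entry_rate_semi + self.entry_rate_curly <= 0:
            raise ParameterError("at least one normal-exit rate must be positive")
        if not (0 <= self.curly_run_prob <= 1):
            raise ParameterError("curly_run_prob must lie in [0, 1]")
        if self.x_rule is not None and self.x_rule < 1:
            raise ParameterError("x_rule must be >= 1 when enabled")

    @property
    def entry_prob_curly(self) -> float:
        """Probability a CCW→CW switch enters curly-1 directly."""
        return self.entry_rate_curly / (self.entry_rate_semi + self.entry_rate_curly)


@dataclass
class ModelParams:
    """Complete simulation parameter set (one record per study)."""

    cb: float = 0.13
    fluctuation: FluctuationParams = field(default_factory=FluctuationParams)
    hill: HillParams = field(default_factory=HillParams)
    motor: MotorParams = field(default_factory=MotorParams)
    waveform: WaveformParams = field(default_factory=WaveformParams)
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.cb <= 1):
            raise ParameterError(f"cb must lie in [0, 1], got {self.cb}")
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")

    # derived printed-table quantities -------------------------------------
    @property
    def k_ccw_cw(self) -> float:
        """CCW→CW rate at the mean wild-type bias, s⁻¹."""
        return self.motor.k_ccw_cw(self.cb)

    @property
    def k_cw_ccw(self) -> float:
        """CW→CCW rate at the mean wild-type bias, s⁻¹."""
        return self.motor.k_cw_ccw(self.cb)

    # serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        known = {"cb", "fluctuation", "hill", "motor", "waveform", "dt"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        sub = {
            "fluctuation": FluctuationParams,
            "hill": HillParams,
            "motor": MotorParams,
            "waveform": WaveformParams,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                extra = set(val) - {f.name for f in sub[key].__dataclass_fields__.values()}  # type: ignore[attr-defined]
                if extra:
                    raise ParameterError(f"unknown keys in {key}: {sorted(extra)}")
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
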