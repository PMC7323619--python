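"""Run configuration.

All thresholds of the decision layer live here: the 10 kcal/mol pre-screen
cut-off applied after the 5-iteration quick optimisation, the 2.4 A maximum
Pd-C bond length that separates a genuine palladated intermediate from a
decomposed one, and the 0 / 5 kcal/mol thresholds on the ipso-complex
stability parameter that partition proton abstraction (PA), ambiguous, and
electrophilic aromatic substitution (SEAr) calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

#: 1 Hartree in kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass(frozen=True)
class PredictorConfig:
    """Tunable parameters of the prediction pipeline.

    Parameters
    ----------
    prescreen_cutoff:
        Energy window (kcal/mol, relative to the group minimum) within which
        quick-optimised intermediates survive the pre-screen. Inclusive.
    quickopt_max_iter:
        Iteration cap of the cheap refinement optimisation.
    pd_c_max:
        Maximum Pd-C bond length (A) for an intermediate to count as a
        stable palladated complex. Inclusive.
    threshold_pa, threshold_sear:
        Boundaries (kcal/mol) on the ipso-complex stability parameter.
        delta < threshold_pa -> PA; delta > threshold_sear -> SEAr;
        the closed interval in between -> ambiguous.
    temperature:
        Temperature (K) used in the Boltzmann product-ratio weighting.
    gas_constant, hartree_to_kcal:
        Physical constants; exposed so reports carry full provenance.
    imaginary_tol:
        Vibrational modes with |frequency| below this value (cm^-1) are
        treated as numerical noise rather than saddle-point evidence.
    displacement_amplitude:
        Step (A, along the normalised imaginary mode) used when resubmitting
        a saddle-point geometry.
    max_retries:
        Remediation budget per intermediate.
    max_conformers, conformer_seed:
        Conformer-generation controls for the structural path.
    metal_basis:
        Basis-set/ECP keyword assigned to Pd in engine decks. The organic
        6-31g(d,p) basis does not define Pd, so this has no silent default;
        deck writing for Pd-containing geometries fails until it is set.
    report_fraction_threshold:
        A site is listed as a predicted product when its Boltzmann fraction
        reaches this value.
    """

    prescreen_cutoff: float = 10.0
    quickopt_max_iter: int = 5
    pd_c_max: float = 2.4
    threshold_pa: float = 0.0
    threshold_sear: float = 5.0
    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL
    hartree_to_kcal: float = HARTREE_TO_KCAL
    imaginary_tol: float = 10.0
    displacement_amplitude: float = 0.3
    max_retries: int = 3
    max_conformers: int = 5
    conformer_seed: int = 2020
    metal_basis: str | None = None
    report_fraction_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.threshold_pa >= self.threshold_sear:
            raise ConfigurationError(
                f"threshold_pa ({self.threshold_pa}) must be below "
                f"threshold_sear ({self.threshold_sear})"
            )
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be > 0 K, got {self.temperature}")
        if self.prescreen_cutoff <= 0:
            raise ConfigurationError("prescreen_cutoff must be positive")
        if self.pd_c_max <= 0:
            raise ConfigurationError("pd_c_max must be positive")
        if self.max_retries < 1:
            raise ConfigurationError("max_retries must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(yaml_text: str) -> PredictorConfig:
    """Build a :class:`PredictorConfig` from YAML text.

    Empty input yields the full defaults. Unknown keys are rejected so a
    typo cannot silently fall back to a default threshold.
    """
    try:
        raw = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(PredictorConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PredictorConfig(**raw)
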