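"""Mechanism classification and regioselectivity prediction.

The decision layer of the pipeline. For every substrate, candidate Pd(OAc)2
intermediates of the two mechanisms (proton abstraction, PA; electrophilic
aromatic substitution, SEAr) are screened in two stages:

1. a pre-screen after the cheap 5-iteration optimisation discards
   intermediates more than 10 kcal/mol above their group minimum;
2. a geometry filter after the full optimisation discards intermediates
   whose shortest Pd-C distance exceeds 2.4 A (no stable Pd-C bond).

Surviving Gibbs energies yield, per mechanism, relative site energies
(minimum exactly 0) and, across mechanisms, the ipso-complex stability
parameter

    delta = [G_min(PA) - G_min(SEAr)] * 627.5095 kcal/mol.

A more stable ipso complex (lower SEAr minimum) gives a larger delta. The
thresholded rule is: delta < 0 -> PA; delta > 5 -> SEAr; 0 <= delta <= 5 ->
both mechanisms plausible. Because the intermediates are assumed close in
energy to their transition states (Hammond postulate), relative intermediate
energies proxy relative kinetic barriers, and product ratios follow from
Boltzmann weighting of the per-site energies.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import softmax

from .chem_structures import (
    AromaticSite,
    Intermediate,
    Mechanism,
    Status,
    Substrate,
    build_all_intermediates,
    enumerate_ch_sites,
    generate_conformers,
)
from .config import GAS_CONSTANT_KCAL, HARTREE_TO_KCAL, PredictorConfig
from .energy_backends import Backend
from .errors import ContractError, DomainError, TableKeyError
from .qc_interface import (
    JobRecord,
    QCTask,
    TaskKind,
    min_pd_c_distance,
    run_remediated_job,
)


class CallBasis(str, enum.Enum):
    THRESHOLD = "THRESHOLD"
    SEAR_ABSENT = "SEAR_ABSENT"
    PA_ABSENT = "PA_ABSENT"


class Call(str, enum.Enum):
    PA = "PA"
    SEAR = "SEAR"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class StabilityParameter:
    """Ipso-complex stability parameter; ``delta`` (kcal/mol) is defined
    only when both mechanisms retain a stable intermediate."""

    delta: Optional[float]
    pa_min_G: Optional[float]  # Hartree
    sear_min_G: Optional[float]  # Hartree


@dataclass(frozen=True)
class MechanismCall:
    call: Call
    basis: CallBasis


@dataclass
class MechanismReport:
    """Per-substrate prediction: site tables, stability parameter, call,
    Boltzmann product fractions, and run provenance."""

    substrate_id: str
    site_energies: dict[str, dict[str, float]]  # mechanism -> h_label -> kcal/mol
    fractions: dict[str, dict[str, float]]  # mechanism -> h_label -> fraction
    stability: StabilityParameter
    call: MechanismCall
    predicted_sites: dict[str, str]  # mechanism -> 0.0-energy h_label
    predicted_products: dict[str, list[str]]  # labels with fraction >= threshold
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "substrate_id": self.substrate_id,
            "site_energies": self.site_energies,
            "fractions": self.fractions,
            "stability": {
                "delta_kcal": self.stability.delta,
                "pa_min_hartree": self.stability.pa_min_G,
                "sear_min_hartree": self.stability.sear_min_G,
            },
            "call": self.call.call.value,
            "call_basis": self.call.basis.value,
            "predicted_sites": self.predicted_sites,
            "predicted_products": self.predicted_products,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_csv_rows(self) -> list[dict]:
        rows = []
        for mech in sorted(self.site_energies):
            fractions = self.fractions.get(mech, {})
            for label in sorted(self.site_energies[mech], key=lambda s: int(s.lstrip("H"))):
                rows.append(
                    {
                        "substrate_id": self.substrate_id,
                        "mechanism": mech,
                        "h_label": label,
                        "rel_gibbs_kcal": round(self.site_energies[mech][label], 4),
                        "fraction": round(fractions.get(label, float("nan")), 6),
                        "predicted": int(label in self.predicted_products.get(mech, [])),
                    }
                )
        return rows


# ---------------------------------------------------------------------------
# screening

def _alive(intermediates: Sequence[Intermediate]) -> list[Intermediate]:
    return [i for i in intermediates if i.status is not Status.DISCARDED]


def prescreen(intermediates: Sequence[Intermediate], cutoff: float) -> list[Intermediate]:
    """Keep intermediates within ``cutoff`` kcal/mol of their group minimum
    (group = substrate x mechanism); the boundary is inclusive. Requires
    quick-optimisation energies on every live input."""
    live = _alive(intermediates)
    groups: dict[tuple[str, str], list[Intermediate]] = {}
    for i in live:
        if i.electronic_energy is None:
            raise ContractError(f"intermediate {i.key} reached prescreen without an energy")
        groups.setdefault((i.substrate_id, i.mechanism.value), []).append(i)
    survivors = []
    for members in groups.values():
        gmin = min(m.electronic_energy for m in members)
        for m in members:
            rel = (m.electronic_energy - gmin) * HARTREE_TO_KCAL
            # inclusive boundary; the 1e-9 kcal pad absorbs the round-off of
            # the Hartree <-> kcal round trip at chemically relevant offsets
            if rel <= cutoff + 1e-9:
                m.status = Status.PRESCREENED
                survivors.append(m)
            else:
                m.discard("prescreen")
    return survivors


def geometry_filter(intermediates: Sequence[Intermediate], pd_c_max: float) -> list[Intermediate]:
    """Keep optimised intermediates with a genuine Pd-C bond
    (distance <= ``pd_c_max`` A, inclusive)."""
    survivors = []
    for i in _alive(intermediates):
        if i.pd_c_distance is None:
            raise ContractError(f"intermediate {i.key} reached the geometry filter without a Pd-C distance")
        if i.pd_c_distance <= pd_c_max:
            survivors.append(i)
        else:
            i.discard("no stable Pd-C bond")
    return survivors


# ---------------------------------------------------------------------------
# decision layer

def relative_site_energies(intermediates: Sequence[Intermediate]) -> Optional[dict[str, float]]:
    """Per-site relative Gibbs energies (kcal/mol) for one mechanism.

    The site energy is the minimum over that site's conformers (ties broken
    by lowest conformer index); the map is shifted so its minimum is exactly
    0.0. Returns None when no intermediate survives, signalling a mechanism
    with no stable intermediate.
    """
    live = _alive(intermediates)
    if not live:
        return None
    mechs = {i.mechanism for i in live}
    if len(mechs) != 1:
        raise ContractError(f"mixed mechanisms in one site-energy group: {mechs}")
    best: dict[str, tuple[float, int]] = {}
    for i in live:
        if i.gibbs_energy is None:
            raise ContractError(f"intermediate {i.key} has no Gibbs energy")
        cur = best.get(i.site.h_label)
        cand = (i.gibbs_energy, i.conformer_index)
        if cur is None or cand < cur:
            best[i.site.h_label] = cand
    gmin = min(g for g, _ in best.values())
    return {label: (g - gmin) * HARTREE_TO_KCAL for label, (g, _) in best.items()}


def stability_parameter(pa_min_G: Optional[float], sear_min_G: Optional[float]) -> StabilityParameter:
    """delta = [G_min(PA) - G_min(SEAr)] * 627.5095 kcal/mol.

    The orientation makes a more stable ipso complex (lower SEAr minimum)
    give a larger delta.
    """
    if pa_min_G is None and sear_min_G is None:
        raise DomainError("no stable intermediates for either mechanism")
    delta = None
    if pa_min_G is not None and sear_min_G is not None:
        delta = (pa_min_G - sear_min_G) * HARTREE_TO_KCAL
    return StabilityParameter(delta=delta, pa_min_G=pa_min_G, sear_min_G=sear_min_G)


def classify_mechanism(sp: StabilityParameter, cfg: Optional[PredictorConfig] = None) -> MechanismCall:
    """Thresholded three-way rule on the stability parameter.

    A mechanism with no stable intermediate forfeits and the other is called
    outright. Both boundaries are inclusive on the ambiguous side: delta
    exactly 0 or exactly 5 is ambiguous.
    """
    cfg = cfg or PredictorConfig()
    if sp.sear_min_G is None and sp.pa_min_G is None:
        raise DomainError("no stable intermediates for either mechanism")
    if sp.sear_min_G is None:
        return MechanismCall(Call.PA, CallBasis.SEAR_ABSENT)
    if sp.pa_min_G is None:
        return MechanismCall(Call.SEAR, CallBasis.PA_ABSENT)
    assert sp.delta is not None
    if sp.delta < cfg.threshold_pa:
        return MechanismCall(Call.PA, CallBasis.THRESHOLD)
    if sp.delta > cfg.threshold_sear:
        return MechanismCall(Call.SEAR, CallBasis.THRESHOLD)
    return MechanismCall(Call.AMBIGUOUS, CallBasis.THRESHOLD)


def boltzmann_fractions(
    ddG: dict[str, float],
    temperature: float = 298.15,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> dict[str, float]:
    """Boltzmann populations from relative Gibbs energies (kcal/mol).

    fraction_i = exp(-ddG_i/RT) / sum_j exp(-ddG_j/RT), evaluated with the
    max-shift (softmax) trick for overflow safety.
    """
    if not ddG:
        raise DomainError("empty energy map")
    if temperature <= 0:
        raise DomainError("temperature must be > 0 K")
    labels = list(ddG)
    x = -np.array([ddG[l] for l in labels], dtype=float) / (gas_constant * temperature)
    fr = softmax(x)
    return {l: float(f) for l, f in zip(labels, fr)}


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _table_driven_intermediates(substrate_id: str, backend: Backend) -> list[Intermediate]:
    """Skeleton intermediates for backends that know their own site labels
    (tabulated/synthetic); no 3D construction is needed because the backend
    supplies energies and Pd-C distances directly."""
    out = []
    misses = 0
    for mech in (Mechanism.PA, Mechanism.SEAR):
        try:
            labels = backend.site_labels(substrate_id, mech.value)  # type: ignore[attr-defined]
        except TableKeyError:
            misses += 1
            continue
        for label in labels:
            site = AromaticSite(atom_index=-1, h_label=label, ring_id=-1)
            out.append(Intermediate(substrate_id, site, mech, 0, geometry=None))
    if misses == 2:
        raise TableKeyError(f"substrate {substrate_id!r} unknown to backend {backend.name!r}")
    return out


def predict(
    substrate: Union[Substrate, str],
    backend: Backend,
    cfg: Optional[PredictorConfig] = None,
    seed: Optional[int] = None,
) -> MechanismReport:
    """Run the full pipeline for one substrate and one energy backend.

    ``substrate`` is either a parsed :class:`Substrate` (sites and
    intermediate geometries are constructed from the structure) or a bare
    substrate id (sites are taken from the backend's own records, the way
    published tables are replayed). Stages: site enumeration -> intermediate
    construction -> quick optimisation + pre-screen -> full optimisation
    with automatic remediation -> Pd-C geometry filter -> relative site
    energies -> stability parameter -> mechanism call -> Boltzmann
    fractions.
    """
    cfg = cfg or PredictorConfig()
    if isinstance(substrate, str):
        sid = substrate
        intermediates = _table_driven_intermediates(sid, backend)
    else:
        sid = substrate.id
        sites = enumerate_ch_sites(substrate)
        confs = generate_conformers(
            substrate, cfg.max_conformers, seed if seed is not None else cfg.conformer_seed
        )
        intermediates = build_all_intermediates(confs, sites)

    quick = QCTask(kind=TaskKind.QUICK_OPT, max_iter=cfg.quickopt_max_iter)
    for i in _alive(intermediates):
        r = backend.evaluate(i, quick)
        if r.converged and r.electronic_energy is not None:
            i.electronic_energy = r.electronic_energy
        else:
            i.discard("quick optimisation failed")

    prescreen(intermediates, cfg.prescreen_cutoff)

    full = QCTask(kind=TaskKind.FULL_OPT_FREQ)
    job_ledger: list[JobRecord] = []
    for i in _alive(intermediates):
        result, records = run_remediated_job(
            intermediate_ref="/".join(i.key) + f"/conf{i.conformer_index}",
            initial_geometry=i.geometry,
            task=full,
            evaluate=lambda geom, attempt, i=i: backend.evaluate(i, full),
            pd_c_max=cfg.pd_c_max,
            max_retries=cfg.max_retries,
            displacement_amplitude=cfg.displacement_amplitude,
            imaginary_tol=cfg.imaginary_tol,
        )
        job_ledger.extend(records)
        if result is None:
            i.discard(records[-1].error_class.value.lower())
            continue
        i.gibbs_energy = result.electronic_energy + (result.gibbs_correction or 0.0)
        i.pd_c_distance = min_pd_c_distance(result.final_geometry)
        if result.frequencies:
            i.imaginary_freqs = [abs(f) for f in result.frequencies if f < 0]
        i.status = Status.OPTIMIZED

    geometry_filter([i for i in intermediates if i.status is Status.OPTIMIZED], cfg.pd_c_max)

    site_energies: dict[str, dict[str, float]] = {}
    fractions: dict[str, dict[str, float]] = {}
    predicted_sites: dict[str, str] = {}
    predicted_products: dict[str, list[str]] = {}
    minima: dict[str, Optional[float]] = {}
    for mech in (Mechanism.PA, Mechanism.SEAR):
        members = [i for i in intermediates if i.mechanism is mech and i.status is Status.OPTIMIZED]
        rel = relative_site_energies(members)
        if rel is None:
            minima[mech.value] = None
            continue
        minima[mech.value] = min(i.gibbs_energy for i in members)
        site_energies[mech.value] = rel
        fr = boltzmann_fractions(rel, cfg.temperature, cfg.gas_constant)
        fractions[mech.value] = fr
        predicted_sites[mech.value] = min(
            (l for l, e in rel.items() if e == 0.0), key=lambda s: int(s.lstrip("H"))
        )
        predicted_products[mech.value] = sorted(
            (l for l, f in fr.items() if f >= cfg.report_fraction_threshold),
            key=lambda s: int(s.lstrip("H")),
        )

    sp = stability_parameter(minima["PA"], minima["SEAR"])
    call = classify_mechanism(sp, cfg)

    return MechanismReport(
        substrate_id=sid,
        site_energies=site_energies,
        fractions=fractions,
        stability=sp,
        call=call,
        predicted_sites=predicted_sites,
        predicted_products=predicted_products,
        provenance={
            "backend": backend.name,
            "deterministic": getattr(backend, "deterministic", False),
            "seed": seed,
            "config": cfg.to_dict(),
            "n_jobs": len(job_ledger),
            "n_intermediates": len(intermediates),
            "n_discarded": sum(1 for i in intermediates if i.status is Status.DISCARDED),
        },
    )
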