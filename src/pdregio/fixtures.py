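"""Bundled worked-example datasets and synthetic input generators.

The published validation data ship as plain-text package data:

* ``paper_tables.csv`` — per-mechanism relative Gibbs energies of the
  heteroaromatic prediction set and the second validation set, as an
  :class:`~pdregio.energy_backends.EnergyTable`;
* ``table1.json`` / ``table3.json`` — the two literature reaction sets
  (conditions, qualitative outcomes);
* ``table2.json`` — published site energies and mechanism calls;
* ``table4.json`` — published stability parameters, Pd-C distances and
  mechanism calls of the second set.

The synthetic generators manufacture energy tables with a known ground
truth and engine logs that exercise each remediation handler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

from .energy_backends import DECOMPOSED_DISTANCE, EnergyTable
from .errors import InputError, PdregioError
from .qc_interface import ErrorClass

_EXPECTED_COUNTS = {"table1": 12, "table2": 8, "table3": 6, "table4": 6}


@dataclass
class FixtureSet:
    """Validated bundle of the published worked examples."""

    table1: list[dict]
    table2: list[dict]
    table3: list[dict]
    table4: list[dict]
    energy_table: EnergyTable

    def __post_init__(self) -> None:
        for name, expected in _EXPECTED_COUNTS.items():
            got = len(getattr(self, name))
            if got != expected:
                raise PdregioError(f"fixture {name} has {got} entries, expected {expected}")
        # minimum of each stable (substrate, mechanism) group is checked by
        # EnergyTable.validate(); cross-check the printed table2 energies
        for entry in self.table2:
            for mech_key in ("pa", "sear"):
                sites = entry[mech_key]
                if sites is not None and abs(min(sites.values())) > 1e-9:
                    raise PdregioError(
                        f"table2 {entry['id']} {mech_key} energies do not reach 0.0"
                    )


def _read_json(name: str) -> list[dict]:
    with resources.files("pdregio.data").joinpath(name).open() as fh:
        return json.load(fh)["entries"]


def paper_energy_table() -> EnergyTable:
    with resources.files("pdregio.data").joinpath("paper_tables.csv").open() as fh:
        return EnergyTable(pd.read_csv(fh))


def load_paper_fixtures() -> FixtureSet:
    """Load and validate the packaged worked-example data."""
    return FixtureSet(
        table1=_read_json("table1.json"),
        table2=_read_json("table2.json"),
        table3=_read_json("table3.json"),
        table4=_read_json("table4.json"),
        energy_table=paper_energy_table(),
    )


# ---------------------------------------------------------------------------
# synthetic energy tables

DeltaDistribution = Union[tuple, Callable[[np.random.Generator], float]]


def _draw_delta(dist: DeltaDistribution, rng: np.random.Generator) -> float:
    if callable(dist):
        return float(dist(rng))
    kind, *params = dist
    if kind == "point":
        return float(params[0])
    if kind == "normal":
        return float(rng.normal(params[0], params[1]))
    if kind == "uniform":
        return float(rng.uniform(params[0], params[1]))
    raise InputError(f"unknown delta distribution {dist!r}")


def make_synthetic_table(
    n_substrates: int,
    n_sites: int,
    delta_distribution: DeltaDistribution,
    decomposed_rate: float = 0.0,
    seed: int = 0,
    threshold_pa: float = 0.0,
    threshold_sear: float = 5.0,
) -> tuple[EnergyTable, pd.DataFrame]:
    """Deterministic synthetic :class:`EnergyTable` plus its ground truth.

    Each substrate gets ``n_sites`` sites per mechanism with relative
    energies starting at exactly 0.0; the SEAR group is offset by -delta,
    delta drawn from ``delta_distribution``. With probability
    ``decomposed_rate`` the whole SEAR group is marked unstable (the ipso
    complex decomposes), forcing a PA call via absence. The returned ledger
    records the true delta and the call it implies under the given
    thresholds.
    """
    if n_sites < 1:
        raise InputError("n_sites must be >= 1")
    if not 0.0 <= decomposed_rate <= 1.0:
        raise InputError("decomposed_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for i in range(n_substrates):
        sid = f"s{i:04d}"
        delta = _draw_delta(delta_distribution, rng)
        sear_decomposed = bool(rng.random() < decomposed_rate)
        for mech in ("PA", "SEAR"):
            rel = np.concatenate([[0.0], np.sort(rng.uniform(0.3, 9.5, n_sites - 1))])
            for k in range(n_sites):
                unstable = sear_decomposed and mech == "SEAR"
                rows.append(
                    {
                        "substrate_id": sid,
                        "mechanism": mech,
                        "h_label": f"H{k + 1}",
                        "rel_gibbs_kcal": float(rel[k]),
                        "pd_c_angstrom": DECOMPOSED_DISTANCE
                        if unstable
                        else float(rng.uniform(2.0, 2.35)),
                        "stable": 0 if unstable else 1,
                        "group_offset_kcal": -delta if mech == "SEAR" else 0.0,
                    }
                )
        if sear_decomposed:
            call = "PA"
        elif delta < threshold_pa:
            call = "PA"
        elif delta > threshold_sear:
            call = "SEAR"
        else:
            call = "AMBIGUOUS"
        truth.append(
            {"substrate_id": sid, "true_delta_kcal": delta, "true_call": call,
             "sear_decomposed": sear_decomposed}
        )
    return EnergyTable(pd.DataFrame(rows)), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# synthetic engine logs

_LOG_GEOMETRY = """\
                         Output coordinates in angstroms

  No.       Tag          Charge          X              Y              Z
 ---- ---------------- ---------- -------------- -------------- --------------
    1 Pd                  46.0000     0.00000000     0.00000000     0.00000000
    2 C                    6.0000     {d:.8f}     0.00000000     0.00000000
"""

_LOG_END = """\
 Total times  cpu:        5.2s     wall:        5.9s
"""


def _freq_block(freqs: Sequence[float]) -> str:
    # 2 atoms -> 6 coordinate rows; the softest mode moves both atoms in x
    lines = [" P.Frequency  " + "  ".join(f"{f:10.2f}" for f in freqs)]
    rows = []
    for r in range(6):
        vals = []
        for k in range(len(freqs)):
            if k == 0 and r in (0, 3):
                vals.append(0.7071 if r == 0 else -0.7071)
            else:
                vals.append(0.01 if r == k % 6 else 0.0)
        rows.append(f"{r + 1:12d}  " + "  ".join(f"{v:10.6f}" for v in vals))
    return "\n".join(lines + rows) + "\n"


def _render_log(error_class: ErrorClass) -> str:
    ok_d, far_d = 2.10, 7.1781
    if error_class is ErrorClass.NONE:
        return (
            _LOG_GEOMETRY.format(d=ok_d)
            + "      Optimization converged\n"
            + " Total DFT energy =     -355.565200\n"
            + " Thermal correction to Gibbs free energy =       0.085000\n"
            + _freq_block([45.10, 210.33, 455.00])
            + _LOG_END
        )
    if error_class is ErrorClass.SADDLE_POINT:
        return (
            _LOG_GEOMETRY.format(d=ok_d)
            + "      Optimization converged\n"
            + " Total DFT energy =     -355.561000\n"
            + " Thermal correction to Gibbs free energy =       0.085000\n"
            + _freq_block([-152.00, 45.10, 210.33])
            + _LOG_END
        )
    if error_class is ErrorClass.DECOMPOSED:
        return (
            _LOG_GEOMETRY.format(d=far_d)
            + "      Optimization converged\n"
            + " Total DFT energy =     -355.571700\n"
            + " Thermal correction to Gibbs free energy =       0.085000\n"
            + _freq_block([38.50, 120.00, 300.00])
            + _LOG_END
        )
    if error_class is ErrorClass.HESSIAN_STALE:
        return (
            _LOG_GEOMETRY.format(d=ok_d)
            + " driver: maximum geometry step exceeded\n"
            + " driver: the Hessian is stale and must be updated before restart\n"
        )
    if error_class is ErrorClass.BAD_GUESS:
        return (
            " Loading initial geometry\n"
            + " guess: failure to perform initial atomic guess\n"
            + " task dft optimize failed\n"
        )
    if error_class is ErrorClass.HARD_FAIL:
        # truncated mid-geometry, as if the scheduler killed the job
        return "\n".join(_LOG_GEOMETRY.format(d=ok_d).splitlines()[:5]) + "\n"
    raise InputError(f"unknown scenario token {error_class!r}")


def make_fixture_logs(scenario: Sequence[Union[str, ErrorClass]]) -> list[str]:
    """NWChem-dialect log texts that parse/classify to the given sequence of
    error classes. The scenario must be non-empty."""
    if not scenario:
        raise InputError("empty scenario")
    out = []
    for token in scenario:
        try:
            cls = token if isinstance(token, ErrorClass) else ErrorClass(str(token))
        except ValueError as exc:
            raise InputError(f"unknown scenario token {token!r}") from exc
        out.append(_render_log(cls))
    return out
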