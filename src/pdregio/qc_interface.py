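"""Quantum-chemistry engine interface: input decks, output-log parsing,
failure classification, and the remediation state machine.

Engine execution itself is out of process and optional; this module only
writes NWChem-dialect input decks and interprets NWChem-dialect output text.
Four failure modes of an intermediate optimisation are recognised and
remediated automatically:

(i)   convergence onto a saddle point: displace the geometry along the
      largest-magnitude imaginary mode and resubmit;
(ii)  optimiser abort after a large geometry step (stale Hessian): resubmit
      from the last coordinates;
(iii) SCF initial-guess failure from a bad starting geometry: discard;
(iv)  decomposed intermediate (no Pd-C bond within the distance cut-off):
      discard.
"""

from __future__ import annotations

import enum
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .chem_structures import Geometry
from .errors import ConfigurationError, NumericError

DEFAULT_FUNCTIONAL = "b3lyp"
DEFAULT_BASIS = "6-31g(d,p)"
QUICKOPT_MAX_ITER = 5


class TaskKind(str, enum.Enum):
    QUICK_OPT = "QUICK_OPT"
    FULL_OPT_FREQ = "FULL_OPT_FREQ"


class ErrorClass(str, enum.Enum):
    NONE = "NONE"
    SADDLE_POINT = "SADDLE_POINT"
    HESSIAN_STALE = "HESSIAN_STALE"
    BAD_GUESS = "BAD_GUESS"
    DECOMPOSED = "DECOMPOSED"
    HARD_FAIL = "HARD_FAIL"


class Action(str, enum.Enum):
    ACCEPT = "ACCEPT"
    RESUBMIT_DISPLACED = "RESUBMIT_DISPLACED"
    RESUBMIT_LAST_GEOM = "RESUBMIT_LAST_GEOM"
    DISCARD = "DISCARD"


@dataclass(frozen=True)
class QCTask:
    """One engine calculation: a 5-iteration quick optimisation used for
    pre-screening, or a full optimisation + frequency/thermochemistry run."""

    kind: TaskKind
    functional: str = DEFAULT_FUNCTIONAL
    basis_main: str = DEFAULT_BASIS
    basis_metal: Optional[str] = None
    max_iter: Optional[int] = None  # None -> 5 for QUICK_OPT, engine default otherwise
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ConfigurationError("multiplicity must be >= 1")
        if self.kind is TaskKind.QUICK_OPT and self.max_iter is None:
            object.__setattr__(self, "max_iter", QUICKOPT_MAX_ITER)


@dataclass
class QCResult:
    """Parsed outcome of one engine run. Total by construction: malformed
    logs yield ``terminated_normally=False`` plus diagnostic text."""

    terminated_normally: bool = False
    converged: bool = False
    final_geometry: Optional[Geometry] = None
    electronic_energy: Optional[float] = None  # Hartree
    gibbs_correction: Optional[float] = None  # Hartree
    frequencies: Optional[list[float]] = None  # cm^-1, negative = imaginary
    normal_modes: Optional[list[list[tuple[float, float, float]]]] = None
    failure_text: str = ""


@dataclass
class JobRecord:
    """One remediation-ledger entry: what happened on one attempt."""

    intermediate_ref: str
    task: TaskKind
    attempt: int
    error_class: ErrorClass = ErrorClass.NONE
    action_taken: Action = Action.ACCEPT


# ---------------------------------------------------------------------------
# deck writing

_METALS = {"Pd"}


def write_deck(geometry: Geometry, task: QCTask, title: str = "pdregio") -> str:
    """Render an NWChem input deck for ``geometry`` and ``task``.

    The organic basis does not cover Pd; a geometry containing Pd therefore
    requires ``task.basis_metal`` (basis/ECP library keyword) to be set.
    """
    if not geometry:
        raise ConfigurationError("empty geometry")
    elements = sorted({el for el, *_ in geometry})
    metals = [el for el in elements if el in _METALS]
    if metals and not task.basis_metal:
        raise ConfigurationError(
            f"no metal basis configured for {metals}; the main basis "
            f"{task.basis_main!r} does not define these elements"
        )

    lines = [
        "echo",
        f'start {re.sub(r"[^A-Za-z0-9_]", "_", title)}',
        f"charge {task.charge}",
        "geometry units angstroms noautosym",
        "  symmetry c1",
    ]
    for el, x, y, z in geometry:
        lines.append(f"  {el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("end")
    lines.append("basis")
    for el in elements:
        lib = task.basis_metal if el in _METALS else task.basis_main
        lines.append(f"  {el} library {lib}")
    lines.append("end")
    lines += ["dft", f"  xc {task.functional}", f"  mult {task.multiplicity}", "end"]
    if task.max_iter is not None:
        lines += ["driver", f"  maxiter {task.max_iter}", "end"]
    lines.append("task dft optimize")
    if task.kind is TaskKind.FULL_OPT_FREQ:
        lines.append("task dft freq")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# log parsing

_ENERGY_RE = re.compile(r"Total DFT energy\s*=\s*(-?\d+\.\d+)")
_GIBBS_RE = re.compile(r"Thermal correction to Gibbs free energy\s*=\s*(-?\d+\.\d+)")
_GEOM_HEADER = "Output coordinates in angstroms"
_CONVERGED = "Optimization converged"
_NORMAL_END = "Total times"
_FREQ_RE = re.compile(r"^\s*P\.Frequency\s+(.*)$")
_FAILURE_HINTS = re.compile(r"(error|fail|abort|stale|exceeded)", re.IGNORECASE)


def _parse_geometry_blocks(lines: list[str]) -> list[Geometry]:
    blocks: list[Geometry] = []
    i = 0
    while i < len(lines):
        if _GEOM_HEADER in lines[i]:
            j = i + 1
            # skip header/separator rows until the first numbered atom line
            geom: Geometry = []
            while j < len(lines):
                m = re.match(
                    r"^\s*\d+\s+([A-Za-z]{1,2})\s+[-\d.]+\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$",
                    lines[j],
                )
                if m:
                    geom.append((m.group(1), float(m.group(2)), float(m.group(3)), float(m.group(4))))
                elif geom:
                    break
                j += 1
            if geom:
                blocks.append(geom)
            i = j
        else:
            i += 1
    return blocks


def _parse_frequency_blocks(lines: list[str], n_atoms: int) -> tuple[list[float], list[list[tuple[float, float, float]]]]:
    freqs: list[float] = []
    modes: list[list[tuple[float, float, float]]] = []
    i = 0
    while i < len(lines):
        m = _FREQ_RE.match(lines[i])
        if not m:
            i += 1
            continue
        block_freqs = [float(t) for t in m.group(1).split()]
        ncols = len(block_freqs)
        cols: list[list[float]] = [[] for _ in range(ncols)]
        j = i + 1
        while j < len(lines):
            row = re.match(r"^\s*\d+\s+((?:-?\d+\.\d+\s*)+)$", lines[j])
            if not row:
                break
            vals = [float(t) for t in row.group(1).split()]
            if len(vals) != ncols:
                break
            for k, v in enumerate(vals):
                cols[k].append(v)
            j += 1
        for f, col in zip(block_freqs, cols):
            freqs.append(f)
            if n_atoms and len(col) == 3 * n_atoms:
                modes.append([(col[3 * a], col[3 * a + 1], col[3 * a + 2]) for a in range(n_atoms)])
            else:
                modes.append([])
        i = j
    return freqs, modes


def parse_result(log_text: str) -> QCResult:
    """Parse an NWChem-dialect output log. Never raises: anything that
    cannot be interpreted comes back as a non-normal termination with the
    offending tail in ``failure_text``."""
    r = QCResult()
    if not log_text or not log_text.strip():
        r.failure_text = "empty log"
        return r
    lines = log_text.splitlines()
    r.terminated_normally = any(_NORMAL_END in ln for ln in lines)

    geoms = _parse_geometry_blocks(lines)
    if geoms:
        r.final_geometry = geoms[-1]
    energies = _ENERGY_RE.findall(log_text)
    if energies:
        r.electronic_energy = float(energies[-1])
    g = _GIBBS_RE.findall(log_text)
    if g:
        r.gibbs_correction = float(g[-1])

    converged_marker = any(_CONVERGED in ln for ln in lines)
    r.converged = bool(
        converged_marker and r.terminated_normally and r.final_geometry and r.electronic_energy is not None
    )

    if r.terminated_normally and r.final_geometry:
        freqs, modes = _parse_frequency_blocks(lines, len(r.final_geometry))
        if freqs:
            r.frequencies = freqs
            r.normal_modes = modes

    if not r.converged:
        hints = [ln for ln in lines if _FAILURE_HINTS.search(ln)]
        tail = lines[-30:]
        r.failure_text = "\n".join(hints) if hints else "\n".join(tail)
    return r


# ---------------------------------------------------------------------------
# geometry helpers

def min_pd_c_distance(geometry: Optional[Geometry]) -> Optional[float]:
    """Shortest Pd-C distance (A), or None if no Pd or no C present."""
    if not geometry:
        return None
    pd = np.array([[x, y, z] for el, x, y, z in geometry if el == "Pd"])
    c = np.array([[x, y, z] for el, x, y, z in geometry if el == "C"])
    if pd.size == 0 or c.size == 0:
        return None
    d = np.linalg.norm(pd[:, None, :] - c[None, :, :], axis=-1)
    return float(d.min())


def displace_along_mode(geometry: Geometry, mode: Sequence[tuple[float, float, float]], amplitude: float) -> Geometry:
    """Move ``geometry`` by ``amplitude`` (A) along the normalised mode.

    Reversible: displacing by +a then -a recovers the input exactly (up to
    floating-point round-off).
    """
    if len(mode) != len(geometry):
        raise NumericError(
            f"mode has {len(mode)} displacement vectors for {len(geometry)} atoms"
        )
    vec = np.asarray(mode, dtype=float)
    norm = float(np.linalg.norm(vec))
    if norm < 1e-12:
        raise NumericError("zero-norm displacement mode")
    step = amplitude * vec / norm
    return [
        (el, x + float(dx), y + float(dy), z + float(dz))
        for (el, x, y, z), (dx, dy, dz) in zip(geometry, step)
    ]


# ---------------------------------------------------------------------------
# failure classification + remediation

def classify_failure(r: QCResult, has_pd_c_bond: bool, imaginary_tol: float = 10.0) -> ErrorClass:
    """Map one parsed result onto the four handled failure modes.

    Pure function: imaginary modes below ``imaginary_tol`` cm^-1 are treated
    as numerical noise, not saddle-point evidence.
    """
    if r.terminated_normally and r.converged:
        if r.frequencies and any(f < -imaginary_tol for f in r.frequencies):
            return ErrorClass.SADDLE_POINT
        if not has_pd_c_bond:
            return ErrorClass.DECOMPOSED
        return ErrorClass.NONE
    text = r.failure_text.lower()
    if "initial guess" in text or "atomic guess" in text:
        return ErrorClass.BAD_GUESS
    if "hessian" in text and ("stale" in text or "update" in text or "step" in text):
        return ErrorClass.HESSIAN_STALE
    return ErrorClass.HARD_FAIL


def _largest_imaginary_mode(r: QCResult) -> Optional[list[tuple[float, float, float]]]:
    if not r.frequencies or not r.normal_modes:
        return None
    idx = int(np.argmin(r.frequencies))
    mode = r.normal_modes[idx]
    return mode if mode else None


def remediate(
    j: JobRecord,
    r: QCResult,
    max_retries: int = 3,
    displacement_amplitude: float = 0.3,
) -> tuple[Action, Optional[Geometry]]:
    """Decide the next step for a job given its classified outcome.

    The action is a pure function of ``j.error_class`` and the attempt
    budget; a resubmittable failure on the last allowed attempt is
    discarded ("max retries").
    """
    cls = j.error_class
    if cls is ErrorClass.NONE:
        j.action_taken = Action.ACCEPT
        return Action.ACCEPT, None
    if cls in (ErrorClass.SADDLE_POINT, ErrorClass.HESSIAN_STALE) and j.attempt < max_retries:
        if cls is ErrorClass.SADDLE_POINT:
            mode = _largest_imaginary_mode(r)
            if mode is not None and r.final_geometry:
                j.action_taken = Action.RESUBMIT_DISPLACED
                return Action.RESUBMIT_DISPLACED, displace_along_mode(
                    r.final_geometry, mode, displacement_amplitude
                )
            # no usable mode information: cannot displace, give up
            j.action_taken = Action.DISCARD
            return Action.DISCARD, None
        j.action_taken = Action.RESUBMIT_LAST_GEOM
        return Action.RESUBMIT_LAST_GEOM, r.final_geometry
    j.action_taken = Action.DISCARD
    return Action.DISCARD, None


def run_remediated_job(
    intermediate_ref: str,
    initial_geometry: Optional[Geometry],
    task: QCTask,
    evaluate: Callable[[Optional[Geometry], int], QCResult],
    pd_c_max: float = 2.4,
    max_retries: int = 3,
    displacement_amplitude: float = 0.3,
    imaginary_tol: float = 10.0,
) -> tuple[Optional[QCResult], list[JobRecord]]:
    """Drive one calculation through the remediation state machine.

    ``evaluate(geometry, attempt)`` produces the next QCResult (an engine
    adapter, a fixture-log stream, or a tabulated/synthetic backend).
    Returns the accepted result (None if discarded) plus the job ledger.
    Terminates in at most ``max_retries`` attempts for any result stream.
    """
    geometry = initial_geometry
    records: list[JobRecord] = []
    for attempt in range(1, max_retries + 1):
        result = evaluate(geometry, attempt)
        d = min_pd_c_distance(result.final_geometry)
        has_bond = d is not None and d <= pd_c_max
        record = JobRecord(intermediate_ref=intermediate_ref, task=task.kind, attempt=attempt)
        record.error_class = classify_failure(result, has_bond, imaginary_tol)
        action, next_geometry = remediate(
            record, result, max_retries=max_retries, displacement_amplitude=displacement_amplitude
        )
        records.append(record)
        if action is Action.ACCEPT:
            return result, records
        if action is Action.DISCARD:
            return None, records
        geometry = next_geometry
    return None, records  # pragma: no cover - loop always exits above


# ---------------------------------------------------------------------------
# optional subprocess adapter (never exercised by the test suite)

class SubprocessEngine:
    """Thin adapter that shells out to a locally installed ``nwchem`` binary.

    Provided for completeness behind the backend contract; desk-scale runs
    use the tabulated or synthetic backends instead.
    """

    name = "engine"
    deterministic = False

    def __init__(self, executable: str = "nwchem", workdir: Optional[str] = None):
        if shutil.which(executable) is None:
            raise ConfigurationError(f"engine executable {executable!r} not found on PATH")
        self.executable = executable
        self.workdir = workdir

    def run(self, geometry: Geometry, task: QCTask) -> QCResult:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            deck = Path(tmp) / "job.nw"
            deck.write_text(write_deck(geometry, task))
            proc = subprocess.run(
                [self.executable, str(deck)], capture_output=True, text=True, cwd=tmp
            )
            return parse_result(proc.stdout + "\n" + proc.stderr)
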