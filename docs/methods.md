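# Methods

## Model

The pipeline rationalises Pd(OAc)₂-catalysed aromatic C–H activation by
comparing the energetics of the first organometallic intermediate of the two
candidate mechanisms at every symmetry-unique aromatic C–H site:

* **PA (proton abstraction / concerted metalation–deprotonation).** The
  Pd–C bond forms concertedly with C–H cleavage; the proton transfers to a
  coordinated acetate. The modelled intermediate has Pd at the site carbon
  with one acetate oxygen directed at the site hydrogen.
* **SEAr (electrophilic aromatic substitution).** Pd(II) attacks the ring
  as an electrophile, giving a Wheland-type *ipso* complex: Pd bound to the
  reacting carbon, that carbon pyramidalised, its hydrogen retained.

The central approximation is the Hammond postulate: these intermediates are
assumed energetically close to their transition states, so *relative
intermediate Gibbs energies proxy relative kinetic barriers*. The pipeline
therefore never locates transition states; this is a deliberate scope
limit, and the predictions are first-approximation kinetic statements, not
barrier heights.

Two derived quantities drive the predictions:

1. **Ipso-complex stability parameter.**
   `delta = [G_min(PA) − G_min(SEAr)] · 627.5095 kcal/mol`, the gap between
   the most stable surviving intermediate of each mechanism. The sign
   convention makes a more stable *ipso* complex give a larger delta. The
   verbal definition of the parameter ("the energy difference between the
   most stable intermediates of the two mechanisms") is sign-ambiguous in
   isolation; this orientation is the only one consistent with both "a more
   stable ipso complex favours the electrophilic mechanism" and the
   published threshold rule, and it reproduces all published calls.
   Classification: `delta < 0 → PA`, `delta > 5 → SEAr`, otherwise both
   mechanisms are regarded as plausible (AMBIGUOUS). A mechanism whose
   intermediates all decompose or are filtered out forfeits, and the other
   is called outright (basis `SEAR_ABSENT` / `PA_ABSENT`).
2. **Boltzmann product fractions.** Within a mechanism, per-site relative
   Gibbs energies ΔΔG (site energy = minimum over that site's conformers;
   map shifted so the minimum is exactly 0) give populations
   `x_i = exp(−ΔΔG_i/RT) / Σ_j exp(−ΔΔG_j/RT)`, evaluated through a
   max-shifted softmax for overflow safety.

## Pipeline and screening

sites → intermediates → quick optimisation → pre-screen → full optimisation
with remediation → Pd–C geometry filter → decision layer.

* **Site enumeration.** One site per aromatic carbon bearing exactly one
  hydrogen; ring N–H/O–H are never sites. Carbons with identical canonical
  symmetry ranks collapse to one representative (benzene has one site,
  pyridine three), avoiding redundant engine jobs. Labels H1…Hn follow
  canonical rank order and are invariant to input atom numbering.
* **Conformers.** ETKDG distance-geometry embedding with 0.5 Å RMSD
  pruning, ranked by MMFF94 energy (UFF fallback), deterministic for a
  given seed. Default retention is 5 conformers (configurable); the
  force-field energy is used only for ranking.
* **Intermediate templates.** Seed geometries only: Pd placed 2.1 Å from
  the site carbon (near typical optimised Pd(II)–aryl distances, so a
  subsequent optimisation converges quickly), acetates idealised
  (C–O 1.25–1.27 Å, O–C–O 124°), PA abstracting oxygen placed on the
  intersection of spheres 2.05 Å from Pd and 1.85 Å from the site H
  (satisfying the ≤ 2.0 Å O···H contact). The metal face is chosen as the
  less crowded side of the ring plane. Placements leaving any two atoms
  closer than 0.7 Å are discarded as clashes. Coordinates are serialised to
  4 decimal places in Å.
* **Pre-screen.** After a 5-iteration quick optimisation, intermediates
  more than 10 kcal/mol above their (substrate × mechanism) group minimum
  are discarded. Both this boundary and the 2.4 Å Pd–C bound are
  *inclusive*: a published site table contains a 10.0 kcal/mol entry, so
  the exclusive reading would contradict it. A 1e-9 kcal/mol pad absorbs
  Hartree↔kcal round-off at the boundary.
* **Geometry filter.** Optimised intermediates whose shortest Pd–C
  distance exceeds 2.4 Å have no stable Pd–C bond and are rejected. "No
  stable intermediate" for a mechanism is decided only after both filters.

## Engine interface and remediation

Decks are written in NWChem dialect: B3LYP, 6-31g(d,p) for main-group
atoms, geometry in Å, `driver maxiter 5` for quick optimisations, and
`task dft optimize` (+ `task dft freq` for the full run). The organic basis
does not define Pd, so the deck writer requires an explicit metal
basis/ECP keyword (`metal_basis`) and refuses Pd-containing geometries
without one — there is deliberately no silent default. Engine execution is
out of process; a subprocess adapter exists behind the backend contract but
desk-scale work uses the tabulated/synthetic backends.

The log parser is total: it extracts termination, convergence, the last
geometry block, the last electronic energy, the Gibbs thermal correction
and the frequency/normal-mode blocks, and maps anything unreadable to a
non-normal termination with diagnostic text. Four failure modes are
remediated:

| outcome | action |
| --- | --- |
| converged onto a saddle point (imaginary mode) | displace 0.3 Å along the largest-magnitude imaginary mode, resubmit |
| optimiser abort after a large step (stale Hessian) | resubmit from the last coordinates |
| SCF initial-guess failure | discard |
| decomposed (no Pd–C bond ≤ 2.4 Å) | discard |

Imaginary modes below 10 cm⁻¹ in magnitude are treated as numerical noise
(standard practice). The retry budget is 3 attempts per intermediate
(configurable); a resubmittable failure on the final attempt is discarded
with reason "max retries". Exhaustive enumeration over all failure
sequences of length ≤ 4 confirms every job terminates in ACCEPT or DISCARD
within the budget.

## Backends and units

Tabulated and synthetic backends store energies as kcal/mol relative values
and convert to an absolute Hartree scale by adding an arbitrary −355.5 Ha
offset, so the downstream code exercises genuine unit conversion
(1 Hartree = 627.5095 kcal/mol; R = 1.987204e-3 kcal mol⁻¹ K⁻¹; standard
state 298.15 K, 1 atm). Published tables print only within-mechanism
relative energies, so the bundled energy table carries an extra
`group_offset_kcal` column: shifting the SEAr group by −delta encodes the
cross-mechanism gap. For the second validation set those deltas are the
published stability parameters; for the heteroaromatic prediction set only
the mechanism call is published, so the stored deltas are fixture
constructions consistent with the call (+7 for SEAr, −3 for PA, +2.5 for
ambiguous) and are flagged as such — no test asserts them.

One bundled record (second-set entry 5) is anomalous in the source: a
positive absolute Gibbs value (presumed sign typo), a 7.1781 Å Pd–C
distance, and a stability parameter inside the ambiguous band despite a
SEAr call. It is stored verbatim with `anomaly_flag=true` and excluded from
replay, not silently corrected.

## Synthetic data generator

The synthetic backend emulates the *decision-layer* statistics of a
screening run, not quantum chemistry: site k of a mechanism gets a relative
energy of k·`site_gap` (default 1 kcal/mol, a typical spacing in the
published site tables), the SEAr group is shifted by −`mech_offset` so the
true stability parameter equals `mech_offset` exactly, Pd–C distances are
drawn uniformly in the stable window 2.0–2.3 Å, and optional Gaussian noise
(sd in kcal/mol) perturbs every site energy through a generator seeded per
(seed, substrate, mechanism, site) — identical across pipeline stages.
`make_synthetic_table` builds whole cohorts with deltas drawn from a point
mass, normal or uniform distribution and a per-substrate probability that
the entire SEAr group decomposes, alongside a ground-truth ledger.

What passing synthetic tests show: the decision layer recovers the
parameters it is fed, exactly at zero noise and degrading monotonically as
noise grows (checked on 200 substrates with deltas uniform on
[−8, 10] kcal/mol at sd ∈ {0, 0.5, 2}). What they do not show: anything
about the accuracy of DFT energies, conformer coverage, or the template
geometries for real substrates — those depend on the engine, which is out
of scope at desk scale.

## Numerical and design choices

* Relative site energies are exact-zero at the minimum by construction
  (differences of identical floats); conformer ties break by lowest
  conformer index.
* Boundary inclusivity: delta exactly 0 or 5 classifies AMBIGUOUS (the
  "between zero and five" band read as closed).
* The Boltzmann temperature defaults to 298.15 K and is overridable per
  run (e.g. to an experimental temperature); the reporting threshold for
  multi-product listings is a 5 % Boltzmann fraction (configurable).
* Validation structures: the two literature reaction sets are depicted
  only graphically in the source, so their records store conditions text
  and qualitative outcomes with `structure_confidence: "none"`, and all
  energy-level checks key off substrate ids. Problem sizes in the test
  suite and acceptance script (200 synthetic substrates, failure sequences
  to length 4, 100 recovery seeds) were chosen as the smallest cohorts
  that make the statistical checks meaningful.
* Reports are pure functions of (substrate set, backend, config): rerunning
  a deterministic backend reproduces byte-identical JSON; run manifests are
  append-only JSON lines and carry config, backend, seed and version.

## Known limitations

* No transition-state search, microkinetics, solvent, oxidant or
  counterion effects; reaction conditions are metadata only.
* Only aromatic C–H sites with exactly one hydrogen; only the
  bis-acetate ligand set; sp³ C–H activation is out of scope.
* The PA acetate is modelled monodentate (κ¹) in the seed geometry; the
  κ²/bridging alternatives are left to the optimiser.
* The quick-optimisation pre-screen assumes the 5-iteration energies rank
  like the final Gibbs energies; in tabulated replays the two coincide by
  construction.
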