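# pdregio

Mechanism classification and regioselectivity prediction for Pd(II)-catalysed
aromatic C–H activation.

Pd(OAc)₂-catalysed C–H functionalisation of (hetero)arenes proceeds through
one of two main mechanisms: **proton abstraction** (PA, also called concerted
metalation–deprotonation: the Pd–C bond forms while an acetate ligand removes
the proton) or **electrophilic aromatic substitution** (SEAr: Pd(II) attacks
the ring as an electrophile, forming a Wheland-type *ipso* complex with the
hydrogen still attached). Which mechanism operates, and which C–H site
reacts, is what a synthetic chemist planning a C–H activation needs to know.

`pdregio` is a desk-scale reimplementation of an automated pipeline that
answers both questions from intermediate energetics rather than transition
states. Because the Pd–substrate intermediates are assumed close in energy
to their transition states (Hammond postulate), relative intermediate Gibbs
energies stand in for relative kinetic barriers.

## The method

For a substrate with symmetry-unique aromatic C–H sites H1…Hn:

1. **Enumerate & build.** 3D conformers are generated from the 2D structure
   (distance-geometry embedding, force-field ranking) and a Pd(OAc)₂
   fragment is attached at every site, once per mechanism (Wheland-type
   *ipso* geometry for SEAr; acetate oxygen poised at the C–H proton for PA).
2. **Screen.** A 5-iteration quick optimisation discards intermediates more
   than **10 kcal·mol⁻¹** above their (substrate × mechanism) group minimum.
   Survivors get a full optimisation + frequency/thermochemistry analysis,
   with automatic remediation of four engine failure modes (saddle point →
   displace along the imaginary mode and resubmit; stale Hessian → restart
   from the last geometry; bad initial guess → discard; decomposed
   intermediate → discard). Optimised structures without a Pd–C bond within
   **2.4 Å** are rejected.
3. **Classify.** The *ipso*-complex stability parameter

   δ = [G<sub>min</sub>(PA) − G<sub>min</sub>(SEAr)] × 627.5095 kcal·mol⁻¹

   is thresholded: δ < 0 → PA, δ > 5 → SEAr, 0 ≤ δ ≤ 5 → both plausible.
4. **Predict products.** Within the called mechanism, per-site relative
   Gibbs energies ΔΔG give Boltzmann fractions
   x<sub>i</sub> = exp(−ΔΔG<sub>i</sub>/RT) / Σ<sub>j</sub> exp(−ΔΔG<sub>j</sub>/RT)
   at T = 298.15 K by default; sites above 5 % population are reported as
   expected products.

Energies come from interchangeable backends: an NWChem deck-writer/log-parser
interface for real engine runs, a **tabulated** backend that replays
published energy tables, and a **synthetic** backend with a known ground
truth for validation.

## Worked example

Replay a bundled heteroaromatic substrate (id `t2e4`) through the full
pipeline against the published energy table:

```
$ pdregio predict --substrate-id t2e4 --backend tabulated --paper-tables --out out/
t2e4: mechanism PA (THRESHOLD), delta = -3.0000 kcal/mol
  PA: most probable site H6 (products >=5%: H6)
  SEAR: most probable site H1 (products >=5%: H1)
```

The stability parameter is negative, so the substrate is called PA; within
the PA site table (H1: 1.9, H5: 9.8, H6: 0.0 kcal·mol⁻¹) site H6 is the
predicted reactive centre, carrying 96 % of the Boltzmann population at
298.15 K (H1: 3.9 %). The JSON/CSV reports and an append-only run manifest
land in `out/`.

The same pipeline runs on a structure you supply:

```
$ pdregio predict --smiles "c1ccc2[nH]ccc2c1" --substrate-id indole \
    --backend synthetic --seed 7 --mech-offset -3 --n-sites 4
indole: mechanism PA (THRESHOLD), delta = -3.0000 kcal/mol
  PA: most probable site H1 (products >=5%: H1, H2)
```

and a stability parameter alone can be classified directly:

```
$ pdregio classify --delta -1.6369
PA
```

Other commands: `pdregio synth table` / `pdregio synth logs` (synthetic
energy tables with ground truth; engine logs replaying failure scenarios)
and `pdregio fixtures show --table N` (the bundled validation data).

## Layout

| module | role |
| --- | --- |
| `pdregio.chem_structures` | substrates, aromatic C–H sites, conformers, Pd(OAc)₂ intermediate templates |
| `pdregio.qc_interface` | NWChem deck writing, log parsing, failure classification, remediation state machine |
| `pdregio.energy_backends` | backend contract; tabulated and synthetic evaluators |
| `pdregio.mechanism_predictor` | screening filters, stability parameter, classifier, Boltzmann fractions, `predict()` |
| `pdregio.fixtures` | bundled validation tables, synthetic table/log generators |
| `pdregio.config` / `pdregio.cli` | YAML run configuration and the `pdregio` command |

See `docs/methods.md` for the scientific and numerical details.
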