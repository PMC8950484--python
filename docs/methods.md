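# Methods

## Scope and model overview

`oglycosim` models mucin-type O-glycosylation of a pooled protein acceptor as
it transits the Golgi of CHO cells. The model begins at the Tn antigen
(GalNAc on Ser/Thr, written `GalNAcol` as in released-glycan MS profiles);
the GalNAc-polypeptide transferase step that creates it is outside scope
because it depends on protein structure and site accessibility, and the >53
potential sites of the PSGL-1-type reporter are treated as one pooled
acceptor. Downstream of Tn, biosynthesis is encoded as 30 reaction rules for
20 enzymes; enzyme families that catalyse one reaction (B3GNT, B4GALT,
ST3GAL, ST6GALNAC) are collapsed into single model enzymes. Six enzymes
act on more than one substrate class and carry suffixed sub-rules
(B3GNT ×3, B3GNT3 ×2, CHST4 ×4, GCNT1 ×2, ST3GAL ×2, ST6GALNAC ×3).

The rule table is data (`data/rules.json`), reconstructed from the enzyme
inventory of the CHO panel (cores/terminal epitopes per enzyme), pathway
narrative and KEGG reaction annotations; any correction is a one-line edit.
An acceptor pattern constrains the residue, its linkage to its parent, root
context, required/forbidden children (one nesting level, enough to express
e.g. "α2,3-sialylated type 2 Gal" for the sialyl-Lewis-x fucosyltransferase)
and terminality; terminality ignores sulfate so a 6-O-sulfated GlcNAc can
still be galactosylated.

## Network generation

Per experiment, the active rules are the transfected enzymes' rules plus the
endogenous helpers required for that line's observed products; the 25
bundled configurations freeze these sets, and a test regenerates the
reachability of every bundled profile structure. The network is the
breadth-first closure from `GalNAcol`: apply every active rule at every
matching unoccupied site, canonicalize, de-duplicate. Closure is confluent —
rule application is a pure function of the substrate — which a test checks
against a randomized-order enumeration. Poly-LacNAc rules make the closure
infinite, so species with ≥ `max_residues` monosaccharides (default 10,
covering every structure in the panel with headroom) are not expanded
further.

## Kinetic model

Four equally sized, well-mixed compartments (cis, medial, trans, TGN), each
2.5 µL, residence time τ = 5.56 min, horizon 4τ = 22.24 min, with the TGN
profile read at the end. Rates follow a rapid-equilibrium bi-substrate
Michaelis–Menten law with acceptor competition:

v = Kf·E·(D/Kmd)·(S_j/Km_j) / [(1 + D/Kmd)(1 + Σ_k S_k/Km_k)],

where the competition sum runs over every (species, rule) pair of the same
enzyme present in the compartment. This form was chosen because it (a) uses
exactly the three named constants Kf, Km, Kmd; (b) reduces to classical
irreversible MM in the saturating-donor, single-substrate limit (verified
against the Lambert-W closed form to <0.1%); and (c) expresses the
substrate competition that shapes this pathway (e.g. core 1 vs core 3
synthesis from Tn). The law lives behind one function so an alternative form
is a local change.

Donors are clamped constants per compartment (µM), supplied only where they
donate: a rule whose donor is 0 in a compartment is silently inactive there.
Enzyme localization is binary: core 1/3 synthesis in cis; core 2/4
branching in medial; elongation and capping in trans+TGN;
fucosyltransferases in medial+trans; the sulfotransferase CHST4 everywhere
except cis. Enzyme concentrations are per-compartment parameters, forced to
0 where the localization is 0.

Transport uses a sequential-batch (plug-flow) schedule by default: each
compartment is integrated alone over its residence window, then its entire
content moves to the next; the hard stop at 4τ motivates this reading. A
continuous CSTR-chain mode (first-order transfer at 1/τ, terminal
accumulation in the TGN) is provided as an option since the historical
compartment models are stirred-tank formulations; the mode is recorded in
the result and the two give deliberately different profiles.

Units: internally everything is µM. The initial glycan concentration is
configured at its conventional face value (100 µmol/µL in cis) and converted
once at the boundary with an explicit factor (1 µmol/µL = 10⁶ µM). Profiles
are relative (%), so the absolute scale cancels; concentrations below
10⁻¹² µM are reported as 0% to suppress integrator noise.

## Numerics

Each compartment's ODE system is compiled to index arrays and integrated
with LSODA (default rtol 10⁻⁸, fitting rtol 10⁻⁷, atol 10⁻¹⁴ of the initial
amount) with an analytic Jacobian. Because kinetic draws span eleven
decades, rare corners of parameter space are pathologically stiff; a hard
budget of 50,000 right-hand-side evaluations per compartment converts such
integrations into a clean `SimulationError` instead of an unbounded solve.
Callers that search parameter space treat these failures as rejected
candidates (objective sentinel +∞) or rejected draws. Mole conservation
(one-to-one reactions, lossless transfer) holds to ~10⁻¹⁵ relative error in
practice and is asserted at 10⁻⁶ across random draws.

## Parameter estimation

Free parameters: per-rule Kf and Km, per-enzyme Kmd, and per-localized-
compartment enzyme concentrations; all searched in [10⁻⁶, 10⁵] on a log₁₀
scale (kinetic constants are scale parameters; the box spans 11 decades).
The objective is Σ_experiments w·Σ_observed (sim% − obs%)², with w = 1/σ²
and σ the standard deviation of the experiment's observed values — the
"standard deviation" weighting convention of common parameter-estimation
tools (w = 1 is available). Observed structures must be species of the
experiment's network; this is validated at problem construction. Matching is
on relative abundance because the experimental profiles are relative MS
intensities; the absolute concentration scale is unidentifiable from such
data.

The optimizer is a (µ, λ) evolution strategy with stochastic ranking,
µ = λ/7, log-uniform initialization, self-adaptive per-coordinate log-normal
step sizes (τ = 1/√(2√n), τ' = 1/√(2n)) and reflection repair at the box.
With bounds enforced by repair all candidates are feasible, so the
stochastic ranking reduces to an objective sort; the ranking machinery is
kept for fidelity to the method. Defaults: population 20, 500 generations,
early stop after 50 generations without 10⁻¹⁰ improvement, optional early
stop when the largest absolute profile residual falls below a target.
Runs are deterministic given the seed. Joint fits share one vector across
experiments; an enzyme absent from an experiment has no reactions in its
network, so its concentration cannot influence that experiment.

## Synthetic data

The panel's measured abundances exist only as figures, so observed profiles
are emulated: ground-truth parameters are drawn log-uniformly inside the
search bounds (enzyme concentrations only where localized), the experiment
is simulated, and the TGN profile becomes the fixture. Draws that leave
>99% of the material as unreacted root are uninformative and are redrawn
(up to 500 attempts; integration failures are rejected the same way).
Optional noise is additive truncated-Gaussian on the percentage scale
(default σ = 0 so recovery tests are exact), renormalized to 100%. The
four-experiment suite (wild type, sialyl-Lewis-x on core 3, sialyl-Lewis-x
on extended core 1, α1,4-GlcNAc on core 1 — the lines with the smallest
profiles) shares a single true vector across all four networks.

What the generator does *not* emulate: measurement noise structure of real
MS intensities (ionization bias is handled separately by the charge
adjustment), replicate variance, missing intermediates, and any systematic
mismatch between the assumed rate law or localization and the cell. Passing
recovery tests therefore shows the estimation machinery is self-consistent,
not that the model is correct for real profiles.

The 25 bundled "observed" fixtures are likewise synthetic stand-ins (flagged
`synthetic: true`): structure lists follow each line's pathway (for the four
modelled lines, the structures reported for those experiments), abundances
are placeholders that sum to 100%.

## Charge adjustment

Negatively charged glycans (NeuAc, NeuGc, sulfate) over-report in MS;
raw intensities are multiplied by 1.0 / 0.3 / 0.4 for charge 0 / 1 / 2 and
renormalized to 100%. Factors for charge >2 are undefined and such entries
are rejected rather than silently scaled. Adjustment applies only to
`raw_intensity` profiles, so double adjustment is impossible by contract.
(The order of scaling vs normalization is immaterial after renormalization.)

## Design choices that were genuinely open

- **Main-chain convention in serialization**: the canonical string continues
  the chain through the deepest child subtree (ties: backbone sugars over
  Fuc/NeuAc/sulfate decorations, then lowest position), which reproduces the
  conventional written forms of sialyl-Lewis-x and the branched cores.
- **Rule-count split**: the 16 sub-rules of the six multi-substrate enzymes
  are split 3/2/4/2/2/3 (B3GNT/B3GNT3/CHST4/GCNT1/ST3GAL/ST6GALNAC); the
  rule file is data so the split is editable. GCNT3 carries a single core-4
  rule; FUT3 a single α1-4 (Lewis-type) rule. NeuGc has a donor entry but no
  dedicated rules, as no NeuGc-containing structure is attested in the panel.
- **Repeat-fit dispersion metric**: fit-to-fit agreement of objectives is
  measured relative to the misfit scale of the data (the objective of the
  no-flux model), since a coefficient of variation is meaningless for a
  quantity whose target is 0; parameter scatter is the median CV of the
  fitted turnover constants.
- **Problem sizes**: the bundled analyses use the wild-type network
  (6 species) for conservation, recovery and repeat-fit experiments, with
  populations of 20–24 and a few hundred generations with early stopping —
  enough for every run to reach residuals far below the 1% reporting
  threshold while keeping a full acceptance run under a minute.

## Known limitations

- No intra-compartment gradients, enzyme recycling/retrograde transport,
  Golgi pH effects, or donor depletion (donors are clamped).
- Site-level heterogeneity of the protein acceptor is pooled.
- The 0.3/0.4 charge factors are taken as given; charge >2 is unsupported.
- Whether the original compartment handoff was batch or continuous is not
  determinable from the sources; both modes are implemented and labelled.
- Identifiability is only characterized empirically (repeat fits), not by
  profile likelihood.
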