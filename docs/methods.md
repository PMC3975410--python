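# Model and methods

`glycodyn` simulates how the extracellular environment of an
antibody-producing mammalian cell culture propagates to the cytosolic
pools of nucleotide sugar donors (NSDs) — the activated sugars
(UDP-GlcNAc, UDP-Gal, GDP-Man, GDP-Fuc, CMP-Neu5Ac, …) that the Golgi
glycosylation machinery consumes. The package couples three layers into
one stiff ODE system, estimates parameters from tidy time-course data,
and quantifies parametric uncertainty with Sobol total-effect indices.
The NSD transport fluxes it exposes are the natural interface to a
downstream Golgi glycosylation model; glycoform prediction itself is out
of scope here.

## Cell-culture layer

An unstructured modified-Monod model over viable cells X_V, dead cells
X_d, extracellular glucose and glutamine, and product titer:

- growth: μ = μ_max · Glc/(K_M,glc+Glc) · Gln/(K_M,gln+Gln)
- death: k_d = k_d,max,glc·K_d,glc/(K_d,glc+Glc) + k_d,max,gln·K_d,gln/(K_d,gln+Gln)
  (inverse Monod — starvation raises death), with dX_d/dt = k_d·X_V
  (no lysis)
- uptake: q_S = μ/Y_Xv/S + m_S; product: q_mAb = Y_mAb/Xv, deliberately
  independent of μ (batch hybridoma titers track integral viable cell
  density)

Balances are written on volume-scaled quantities (V·X_V, V·[S], …), so
fed-batch dilution with piecewise-constant F_in/F_out needs no extra
terms; feeds enter as +F_in·[S_feed]. Lactate and ammonia are not state
variables: for this cell system they were found not to influence growth
or death, so nothing downstream consumes them.

Numerical positivity: each substrate consumption term carries a smooth
guard S/(S+ε) with ε = 10⁻⁶ mM. Above ~1 nM the guard is unmeasurably
close to 1; at depletion it shuts uptake off instead of driving the
concentration negative. The same guard gates the glucose inlet of the
NSD layer so the two stay consistent.

## Nucleotide layer

Six pools (ATP, ADP, AMP, CTP, GTP, UTP) connected by eight lumped
Monod-form reactions; glucose and glutamine enter through their
*extracellular* concentrations (the reduced network treats them as
upstream supply signals, not tracked substrates). Four rate-law classes:
nucleotide-only, nucleotide×Gln, nucleotide×Glc and Glc×Gln (de-novo
synthesis). The default wiring — ATP→ADP, ADP→AMP (nucleotide-only);
AMP→ADP, ADP→ATP (×Glc); de-novo ATP and UTP (Glc×Gln); UTP→CTP (×Gln);
de-novo GTP with an ATP saturation factor as its purine-precursor
proxy — is configuration-overridable, as the original network diagram is
not uniquely specified in text.

Growth-coupled outlets for AMP, CTP, GTP and UTP drain the pools into
DNA/RNA synthesis:

    F_out,nuc = Nuc/(K_TP+Nuc) · μ · (DNA_f·m_DNA/Mr_DNA + RNA_f·m_RNA/Mr_RNA) / V_cell

with m_DNA = 7.05 and m_RNA = 28.55 pg/cell. The printed form of this
outlet multiplies by the cell volume; read literally that leaves the
balance dimensionally inconsistent, so the per-cell monomer demand is
divided by V_cell to give mM/h of cell volume — an interpretation, not a
change of the science. Thymidine demand is booked against the UTP pool.
Monomer fractions default to murine GC content (DNA A=T=0.29, G=C=0.21)
and a typical mammalian RNA composition, with fraction-weighted monomer
masses Mr_DNA = 308.9 and Mr_RNA = 322.1 mg/mmol; all are config-editable
placeholders. The NSD layer reports its UTP/GTP/CTP consumption
(pyrophosphorylase and CMP-transferase fluxes) back to this layer as
drains; ATP consumed by sugar kinases is considered covered by the lumped
adenylate interconversions.

With outlets and drains disabled the wiring conserves total adenylate up
to de-novo input exactly; this is a structural test of the bookkeeping.

## NSD synthesis layer

34 dynamic sugar/sugar-phosphate/nucleotide-sugar species, assembled from
the murine KEGG nucleotide-sugar pathways: the hexose trunk
(Glc→Glc6P→Fru6P/Glc1P), UDP-Glc/UDP-Gal/UDP-GlcA/UDP-Xyl, the
hexosamine branch to UDP-GlcNAc/UDP-GalNAc, the sialic branch
(ManNAc→…→CMP-Neu5Ac), the mannose/fucose branch
(Man6P→GDP-Man→GDP-Fuc), and salvage entry points (Gal, GlcN, GlcNAc,
GalNAc, Fuc, Fru). Nine non-NSD co-substrates (PEP, pyruvate, glutamate,
acetyl-CoA, PPi, Pi, NAD⁺, NADH, H₂O) are held constant; nucleotides are
boundary species supplied by the nucleotide layer; intracellular
glutamine is assumed to track intracellular glucose (no data to
constrain it separately).

69 distinct reactions are simulated: 35 primary enzymatic steps,
24 reverse/parallel enzymatic reactions, 9 Golgi/ER transports and the
glycolysis outlet. The enzymatic mechanism census is 20 uni-uni,
7 random-order bi-bi, 14 ordered bi-bi, 17 ping-pong bi-bi and one
ping-pong ter-ter (UDP-glucose dehydrogenase, which consumes two NAD⁺
per UDP-Glc). Reverse reactions are assigned to the mutases, epimerases
and isomerases (uni-uni) and to the transferase/pyrophosphorylase family
(whose substituted-enzyme reverse keeps the ping-pong form); parallels
are isoenzymes and the hexosamine-recycling deacetylases. Since the
original supplementary material enumerating reaction-by-reaction
mechanisms is not available, this assignment is a documented
reconstruction; the counts are the contract and the roster is
config-editable.

Rate laws are the standard saturation-kinetics forms (see
`glycodyn.rates`), with textbook modifier algebra applied term-wise:
competitive inhibition scales the target substrate's Km by (1+ΣI/K_i),
non-competitive scales the rate, un-competitive scales the
fully-substrate-bound denominator term (for the ter-ter case the
inhibitory factor sits on the Km_A·B² term, following the printed law —
the default network places UDP-Xyl feedback on UDP-glucose dehydrogenase
there). Allosteric activation multiplies E₀ by the activator's
saturation factor; cooperative substrates replace [A]/(K+[A]) with
[A]ⁿ/(Kⁿ+[A]ⁿ). The default network carries 76 inhibitory terms
(product inhibitions on every enzymatic reaction, pathway feedbacks such
as UDP-GlcNAc⊣GFPT, CMP-Neu5Ac⊣GNE, GDP-Fuc⊣GMDS, and ADP energy-charge
terms on six kinases), 5 activations and 6 Hill species on the committed
steps of the UDP-GlcNAc and CMP-Neu5Ac branches. Which steps carry the
modifiers is another documented reconstruction.

### Demand, transport and salvage

Each transporter runs at

    v_T = NSD/(K_TP+NSD) · [μ·N_gly,cell·N_NSD,gly + q_mAb·N_gly,mAb·N_NSD,mAb] / V_cell

The host demand coefficients come from the mature human B-cell glycoform:
N-linked and O-linked glycans at 1.41×10⁻⁸ and 1.31×10⁻⁸ μmol/cell
(2.72×10⁻⁸ total), with abundance-weighted mean sugar counts per glycan
(GlcNAc 1.576, GalNAc 0.482, Man 3.013, Gal 0.950, Neu5Ac 1.011,
Fuc 0.172). Note the published prose attaches the larger abundance to
the O-linked row, but the published averages only reproduce with the
larger weight on the N-linked row; the arithmetic wins. The product term
uses two Fc N-glycans per antibody and a typical core-fucosylated
biantennary murine IgG1 glycan (placeholder, replaced by a measured
glycoform via config). UDP-GlcA/UDP-Xyl transports get small
glycosaminoglycan demand coefficients (0.05/glycan each, placeholder) so
their branch has a sink. The CMP-Neu5Ac transporter's K_TP is scaled by
(1 + ([UDP-GlcNAc]+[UDP-GalNAc])/K_i), the known UDP-HexNAc competitive
inhibition.

Four UDP-Glc are consumed per N-glycan in the calnexin/calreticulin
cycle and their glucose units return to the intracellular Glc pool;
mannose trimming returns (9 − mean Man per glycan) units per N-glycan.
Because the demand coefficient uses the *final* mean mannose count while
salvage is referenced to the 9-mannose precursor, the printed arithmetic
leaves a small net mannose surplus; it recycles through the
mannose-6-phosphate isomerase back to Fru6P and exits through
glycolysis, so mass closure is unaffected. This bookkeeping subtlety is
inherited from the source arithmetic and kept as printed.

The glycolysis outlet (Fru6P → Fru-1,6-bisP, Hill-type irreversible with
enzyme level E_glyc) is the dominant sink: under the default calibration
it consumes 97.2–98.7% of the glucose inlet flux q_glc/V_cell at every
output time, consistent with the expectation that only a few percent of
hexose flux feeds the NSD network.

### Units and conversions

Package-wide units: h, mM, L, cells/L, mmol. Intracellular
concentrations are mM of aggregate cell volume; a per-cell molar flux f
(mmol/(cell·h)) converts to a concentration rate f/V_cell, independent of
cell number. V_cell defaults to 1.2×10⁻¹² L (placeholder). All per-cell
↔ volumetric conversions go through this single convention.

## Initialization and integration

Measured species (the seven NSDs with assay data) start at their
configured initial concentrations; the remaining 27 intermediates are
solved so that their time derivatives vanish at t=0 with the culture and
nucleotide layers frozen (Powell hybrid root-finding with multistart and
a bounded least-squares fallback; residual tolerance 10⁻⁶ mM/h; warm
starts reuse the previous solution). Salvage-entry sugars with no
intracellular source (Gal, GlcN, GlcNAc, GalNAc, Fuc, Fru) legitimately
sit at zero in unsupplemented batch culture; their kinases are
structurally present and become active under feeding scenarios.

The coupled 46-state system is stiff (trunk enzymes turn over in
milliseconds-scale characteristic times against a 120 h horizon).
Default integrator: LSODA at rtol 10⁻⁸ with a scale-aware absolute
tolerance (atol 10⁻¹² times a per-state magnitude scale, since cell
counts and concentrations differ by eight orders of magnitude). Radau
and BDF are available; LSODA and Radau agree to better than 10⁻⁶
relative on every concentration above a 10⁻³ mM floor (below that floor
both answers are numerically zero and relative error is meaningless).
Rates vanish with their substrates by construction, so trajectories stay
non-negative without clipping; state unpacking additionally caps probe
values (10⁹ mM / 10¹⁶ cells/L) because implicit solvers evaluate the
RHS far outside the physical region during Newton iterations.

Per-timepoint diagnostics: the glycolysis fraction (outlet / glucose
inlet) and a flux-closure residual (inlet + salvage − outlet − transports
− accumulation, relative); closure holds to machine precision because
every enzymatic reaction conserves the sugar moiety count, making the
residual a pure implementation audit.

## Calibration

The estimation contract is χ²(θ) = Σ((y_model−y)/sd)² over a tidy
dataset; sd defaults to 10% of the value when absent. Minimization uses
bounded trust-region least squares on log10-transformed parameters
(kinetic constants are uncertain on ratio scales) with Latin-hypercube
multistart; the nominal vector is always the first start, simulation
failures are penalized rather than fatal, and every start's outcome is
logged. The default 46-parameter free set mirrors the study design:
30 distinct enzyme concentrations (reactions sharing an enzyme share its
E₀), 8 dissociation constants and 7 turnover rates on branch-committing
steps, and the GFPT Hill coefficient; exact membership ships in the
config and is flagged as a reconstruction. When the free set and the
observables touch only the culture layer, a fast growth-only integration
is used.

On noise-free synthetic culture data the three-parameter growth set is
recovered to ~10⁻⁴ % from a 1.5× offset start; at 5% multiplicative
noise the 46-parameter fit at reduced multistart reaches the noise-floor
objective (these are the package's acceptance checks — see below for
what they do and do not show).

## Sensitivity analysis

Total-effect Sobol indices are estimated directly on the model (not on a
metamodel) with the Saltelli radial design — N(k+2) evaluations from a
scrambled Sobol' sequence — and the Jansen estimator, with bootstrap
confidence intervals over sample rows. Parameter ranges default to
×/÷10 around nominal, log-uniform (ranges are not published; this is a
package default). The design intent is the 46-parameter set against the
seven NSD concentrations at 20/40/60/80/120 h, with indices above 0.036
(the smallest experimental error of the NSD assay) deemed significant;
E_glyc is excluded because it dominates every output. The published
analysis used N = 2¹⁷ through an RS-HDMR metamodel; here N is
configurable and 2¹⁷ remains selectable where the compute exists. During
GSA the initial intermediate concentrations are held at the
nominal-parameter steady state (initial conditions are data, not
functions of the sampled kinetic parameters), making each evaluation a
single forward integration.

The estimator is validated against the closed-form Ishigami indices
(0.557/0.442/0.244 at a=7, b=0.1) at N=2¹², inert-parameter and symmetry
properties, and a smoke-scale run on the coupled ODE model.

## Synthetic data

No raw measurements are distributed with the underlying study, so the
generator is the package's testing surface. It emulates a 400 mL, 120 h
batch hybridoma culture seeded at 2×10⁵ cells/mL in 25 mM-glucose /
4 mM-glutamine medium, sampled every 12 h, with the observable panel of
the reported experiments (culture panel, six nucleotides, seven NSDs).
Noise is multiplicative log-normal, mean-unbiased, with class CVs of 10%
(cell counts), 5% (extracellular metabolites) and 8% (nucleotides/NSDs),
and a 0.036 mM floor on recorded NSD standard deviations. Records below
a per-variable detection limit (default: GDP-Fuc at 0.036 mM, the
species reported to fall below detection) are flagged as censored and
carry the limit as their value.

What passing tests show: the pipeline (structure → simulation →
calibration → GSA) is self-consistent and recovers known truths from
data with the reported sampling structure. What they do not show:
agreement with the original wet-lab trajectories (not deposited) or the
correctness of any placeholder kinetic constant — every Km/kcat/Ki/E₀
in the shipped config is marked `provenance: placeholder` and is meant
to be overwritten by calibration against real data.

## Default calibration of the placeholders

The shipped constants were chosen once so the default configuration is a
coherent study condition: the t=0 steady state solves with physiological
intermediate levels; pools stay bounded and non-negative over 120 h; the
glycolysis split stays above 95.8% at all times; and enzyme levels start
from the 3.9 μM average cytosolic enzyme concentration estimate with
kcat values in the 10²–10⁵ h⁻¹ range. Nucleotide initial values sit at
their quasi-equilibrium (a cold adenylate start throttles hexokinase
through its ADP term and transiently distorts the glycolysis split). The
late-culture collapse of UDP-sugar pools after glutamine exhaustion is a
genuine prediction of the default parameterization — UDP-HexNAc
synthesis is glutamine-dependent — not a numerical artifact.

## Known limitations

- Nucleotide and NSD outlet fluxes are functions of growth rate only;
  decoupling them (e.g., via flux balance constraints) is future work
  noted in the source study as well.
- The mechanism-to-reaction assignment, modifier placement, constant
  pool roster and all kinetic constants are reconstructions or
  placeholders where the original supplements are unavailable; the
  structural counts, rate-law algebra and demand arithmetic are the
  tested contract.
- Amino-acid nitrogen sources beyond glutamine (asparagine, glycine) are
  not represented.
- Fed-batch support is limited to piecewise-constant flows; feed pulses
  as events are not handled.
- The simulation-scale defaults used in tests (reduced multistart,
  moderate Sobol sample sizes, 12 h sampling) are the package's own
  desk-scale study conditions; cluster-scale settings (N = 2¹⁷, large
  multistart) are configuration choices, not code changes.
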