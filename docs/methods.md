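# Methods

## Scope and model

`pepion` analyses conformer ensembles of free amino acids and their
"dipeptides" (N-terminally acetylated, C-terminally amino-methylated amino
acids) and of their complexes with the divalent cations Ca²⁺, Ba²⁺, Sr²⁺,
Cd²⁺, Pb²⁺ and Hg²⁺.  The study grid is 20 side chains × 2 backbone types ×
7 complexation states = 280 systems at the default protonation level; five
side chains (Arg, Lys, His, Asp, Glu) contribute a protonated variant each
when protomers are enabled.

Each conformer is a Cartesian geometry with a total energy in eV.  The
analysis is purely geometric and energetic: no electronic-structure
quantities are computed, and the Hg²⁺ coordination anomaly is treated only
through its geometric fingerprint (two ligands pulled markedly closer than
the rest).

## Structure classification

All class assignments are deterministic decision rules over measured
geometry; every label carries the supporting measurements as evidence.

* **Proton assignment.**  Each hydrogen is assigned to its nearest heavy
  atom; if the two nearest heavy atoms differ by less than 0.15 Å the proton
  is flagged *shared* (the shared acidic proton between the carboxyl and
  amino functions), and a hydrogen with no heavy atom within 1.3 Å is an
  *orphan*.
* **Free amino acids.**  Carboxylate deprotonated + acidic proton on a
  nitrogen → *zwitterionic* (the donor may be the backbone N or a basic
  side-chain N, which keeps the three-class scheme closed for
  arginine-like side chains).  Neutral backbone with the carboxyl O–H
  donating to the amino N → *type II*; neutral backbone with an amino N–H
  donating to the carbonyl O → *type I*; otherwise *other*.
* **Amino acid + cation.**  Zwitterionic backbone with the cation within the
  coordination cutoff of a carboxylate O → *salt bridge*; neutral backbone
  with the cation within cutoff of both the amino N and a carbonyl O →
  *charge solvated*.
* **Dipeptides.**  A hydrogen bond from the residue amide N–H to its own
  carbonyl O closes a 5-membered pseudocycle → *C5*; from the C-cap amide
  N–H to the acetyl O, a 7-membered pseudocycle → *C7*, split into *C7ax* /
  *C7eq* by side-chain orientation.  When both contacts exist the shorter
  H···A distance wins.
* **Dipeptide + cation.**  A cation within cutoff of both the acetyl O and
  the residue carbonyl O closes the otherwise incomplete 7-ring → *iC7ax* /
  *iC7eq*.  A glycine-type residue has no Cβ, hence no axial/equatorial
  label; such bridged complexes fall into *other* with explanatory evidence.

Pseudocycle size counts the heavy ring atoms plus the closing hydrogen or
cation, reproducing the customary C5/C7 naming.  Side-chain orientation is
the angle θ between Cα→Cβ and the normal of the least-squares ring plane;
θ < 45° is axial.  The 45° split is the symmetric, parameter-free choice.

### Numeric criteria

| quantity | default | note |
|---|---|---|
| H-bond H···A | ≤ 2.5 Å | generic intramolecular criterion |
| H-bond D···A | ≤ 3.5 Å | |
| H-bond ∠DHA | ≥ 120° | |
| C5 contact | ≤ 2.7 Å, ∠ ≥ 95° | the C5 contact is long and strongly bent; both relaxations follow common practice for this motif |
| free-amino-acid ring contacts | ∠ ≥ 95° (via the C5 criteria set) | the 5-ring type I/II contacts are equally bent |
| covalent H assignment | ≤ 1.3 Å, shared band 0.15 Å | |
| coordination cutoff | Shannon radius + 1.52 Å + 0.4 Å | 1.52 Å is an O radius proxy; per-element overrides accepted |
| hierarchy deduplication | 0.3 Å heavy-atom RMSD | lowest-energy representative kept |
| histogram | 1.8–3.6 Å, bin 0.05 Å, KDE bandwidth 0.08 Å | |

All criteria are configurable through the pipeline configuration and are
echoed (via the configuration hash) into every report file.

Torsions follow the IUPAC sign convention on (−180°, 180°].  Ramachandran
quadrants are the four sign quadrants of (φ, ψ); values exactly on a border
(0 or ±180°) are assigned to the adjacent quadrant in the clockwise sense
and flagged, since no border convention is canonical.

## Energetics

Energies are stored in eV; kJ/mol values use the fixed factor 96.485
(the customary rounding in which ~4 eV ≙ ~400 kJ/mol), making the
round-trip conversion exact.  Binding energies are

    E_bind = E(ligand, global minimum) + E(ion) − E(complex, global minimum),

positive when the bound complex lies below the separated constituents, so
"strongest first" rankings sort descending.  When a ligand has both a
zwitterionic and a neutral minimum the overall global minimum is the
reference and its class is recorded.  Protomer pairs (e.g. Lys/LysH) are
reported as separate ligand rows.  Rank agreement between ion series uses
Kendall τ-b (tie-corrected, appropriate at n = 10–20 ligands), together
with the maximum absolute binding-energy deviation — the quantity behind
the calcium/lead mimicry observation.

## Coordination profiles

Coordination shells collect all N/O/S atoms within the cutoff, tagged by
element and sorted by distance.  Cation–O distances pooled over the
lowest-energy conformers are binned, and modality is decided by counting
local maxima of a Gaussian-kernel density (maxima closer than the bandwidth
merged).  A smoothed-maximum count was chosen over a statistical dip test
because it is deterministic and directly explainable, which is all the
unimodal (Cd-like) vs multimodal (Hg-like) contrast requires.

## Toxicity reference data

The packaged table carries, per ion: the Shannon octahedral radius, the
standard hydration enthalpy, and the LD₅₀ of the chloride salt, each with a
citation string; the barium LD₅₀ is an interval (100–300 mg/kg) and enters
the correlation through its geometric mean.  The binding/toxicity report is
the Kendall τ between mean binding energy and LD₅₀ plus a leave-one-out
scan; the ion whose removal most increases |τ| is flagged as the trend
outlier (barium, whose toxicity stems from potassium-channel interference
rather than protein binding).

## Synthetic benchmark

The generator builds simplified surrogates — united heavy atoms, explicit
polar hydrogens, 0–2 side-chain torsions with terminal groups spanning
methyl, hydroxyl, thiol, carboxylate/carboxylic acid, amide and
amine/ammonium — by sequential internal-to-Cartesian placement, so requested
torsions are realized to < 10⁻⁶ degrees.  Energies come from a screened
Coulomb (ε = 4) + Lennard-Jones + hydrogen-bond-well potential.  Toy ion
parameters are charge +2 with effective radii following the packaged
Shannon ordering; the cation–O contact distance is radius + 1.35 Å.  Pb²⁺
deliberately shares Ca²⁺'s toy radius, so the two binding series coincide
exactly, and Hg²⁺ carries an extra short-range attraction toward its two
nearest oxygens (contact 2.08 Å) as the geometric surrogate of its
covalency-driven coordination change.

Ensembles are built from named geometric recipes whose class labels are
known by construction.  Each system designates a global-minimum class;
competitor and decoy conformers are admitted only when their energy lies
above the designated minimum, and recipes that would undercut it are
excluded from that system (e.g. the bare zwitterion for type-II-preferring
surrogates — mirroring the fact that the gas-phase zwitterion is not always
a stable minimum, and the C7 basin for bulky, C5-preferring surrogates).
Cation ensembles are truncated until their deduplicated conformer count is
strictly below the matching bare ensemble, so the conformational-space
contraction holds for every system and seed.  Small seeded torsional jitter
(±2°) decorates the bare ensembles; cation complexes of one ligand share a
seeded stream so ions with equal toy parameters receive identical
geometries.  Three surrogates (Ser-, Asp- and Asn-like) bind the cation
tridentately in the capped form: for Hg the side-chain oxygen is rotated
(grid + golden-section scan on one torsion) to a 2.62 Å contact — the
ionic-distance population alongside the two short bonds that makes the Hg
histogram bimodal — while for all other ions the side chain stays extended
with its oxygen beyond the 3.6 Å histogram range, keeping their pooled
distributions unimodal.

A torsional basin-hopping search over the same toy potential (random
perturbation, Nelder–Mead local minimization, Metropolis acceptance on
minimized energies at 0.2 eV, minima deduplicated at 20° torsion distance)
is provided for open-ended conformer generation and is validated against a
grid scan on a one-torsion restriction; the benchmark suite itself uses the
constructive recipes for speed and exact label control.

**What the suite does and does not emulate.**  It reproduces the structural
taxonomy, the contraction of conformational space under cation binding, the
radius-driven binding order Ba < Sr < Ca ≈ Pb < Cd < Hg, the exact Ca/Pb
concordance, and the Cd/Hg modality contrast.  It does not emulate
first-principles energetics, realistic conformer counts (hundreds per
flexible side chain), solvent, temperature or entropy, and its 100% class
recovery reflects well-separated constructed geometries — real ensembles
contain borderline structures that no fixed geometric criterion classifies
perfectly.

## Problem sizes

The default benchmark covers 10 surrogate ligands (including two protonated
variants) × 2 backbones × 7 complexation states = 140 systems, with up to 6
bare and 3 complexed conformers per system after selection.  These sizes
keep full multi-seed verification runs in the tens of seconds while every
trend the analysis asserts is exercised; they are generator parameters and
can be raised freely.

## Known limitations

* Bond perception is distance-based (covalent radii + 0.45 Å); no
  aromaticity or bond orders.
* RMSD is not symmetry-corrected, so chemically equivalent atom
  permutations are treated as distinct; hierarchy deduplication therefore
  slightly undercounts duplicates of symmetric side chains.
* The quadrant border convention and the pseudocycle member-counting
  convention (heavy atoms + closing H/cation) are package choices,
  documented above, where no canonical definition exists.
* The external-database validation path (`pepion validate`) reports raw
  counts and the zwitterion/neutral preference only; it requires the
  separately deposited first-principles conformer set and is not exercised
  by the bundled tests.
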