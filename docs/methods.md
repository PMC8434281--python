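# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline uses them.

## Coordinate model and conventions

Coordinates are in Å; author residue numbering (with insertion codes) is
the public identifier. Hydrogens are dropped on read — crystal structures
rarely resolve them — and every hydrogen needed later (His Hε1, backbone
amide H) is rebuilt geometrically with standard bond lengths (C–H 1.08 Å,
N–H 1.01 Å). Alternate locations resolve to the highest-occupancy
conformer, ties broken by the alphabetically first altloc tag, so repeated
reads of one file always yield the same torsions.

Dihedrals follow the standard protein convention (the two-plane atan2 form;
trans ω = 180°, right-handed α-helix φ ≈ −57°). χ1 rotamers are binned as
g+ on [0°, 120°), g− on (−120°, 0°), trans elsewhere; the bins partition
the circle with no gaps and reproduce the conventional labels for all the
survey's printed values (e.g. 72° → g+, 179° → trans, −58° → g−, 93° → g+).
Angle statistics are always circular (scipy `circmean`/`circstd`); nothing
averages angles naively, so a cluster containing {175°, −179°} reports a
mean of 178°, not −2°.

## Motif mining

A zinc site is a Zn atom with its heavy-atom ligand inventory within a
coordination cutoff, default 3.0 Å. The cutoff is a documented default, not
a literature value: it covers the observed Sγ–Zn (2.34 ± 0.07 Å) and
Nδ1–Zn (2.1 ± 0.1 Å) bond-length distributions with margin while excluding
second-shell contacts. Carbon and hydrogen are never counted as ligands.

A motif is a five-residue window, Cys at i and His at i+3, consecutive in
author numbering with no insertion codes inside the window, whose Cys Sγ
and one His ring nitrogen coordinate the *same* zinc. The binding nitrogen
is the nearer of Nδ1/Nε2; when the two distances differ by less than 0.1 Å
the motif is flagged tautomer-ambiguous instead of guessed. The α-turn gate
keeps motifs with Cα(i)–Cα(i+4) ≤ 7 Å, boundary inclusive. Deduplication
keeps one representative per distinct five-letter sequence — the motif with
the lexicographically smallest (structure id, chain, start) key — so reruns
are reproducible.

## Torsions, turn type, hydrogen bonds

χ1(Cys) = N-Cα-Cβ-Sγ and χ1(His) = N-Cα-Cβ-Cγ; φ/ψ are standard. The IαRS
α-turn label is assigned when each of the six backbone torsions of
residues i+1..i+3 lies within ±40° (circularly) of the template
(−59, −37, −65, −47, −79, −21) — the circular means of the dominant
cluster. The tolerance is configurable; ±40° admits all four cluster means
while rejecting extended backbones.

The i→i+4 hydrogen bond uses a geometric criterion: d(O_i···N_{i+4}) ≤
3.5 Å and ∠(C=O···N) ≥ 90°, plus ∠(N–H···O) ≥ 120° with a geometrically
built amide H when residue i+4 is not proline. A DSSP-style energy
criterion was deliberately not used; the distance/angle gates are the
common practice for survey work and need no charges.

## Metal-site geometry and chirality

For a 4-ligand site the package reports the four bond lengths, the six
inter-ligand angles at the metal, and a *tetrahedricity* score — the mean
absolute deviation of those angles from 109.47°. An ideal tetrahedron
scores 0; a square-planar arrangement scores 36.49°.

Λ/Δ chirality of a two-pair site uses the skew-line convention: with
u₁ = unit(S₁→N₁), u₂ = unit(S₂→N₂) and d the unit vector between the pair
midpoints, the sign of d·(u₁×u₂) is invariant under swapping the pairs and
flips under mirror reflection. The sign→label calibration (positive = Λ) is
anchored by the 4ijd_A dimer reconstruction, the one whose inter-chain
Hε1→HN distance independently matches its published 6.0 Å value.

## RMSD clustering

Pairwise RMSDs are computed after per-pair Kabsch superposition (SVD, with
the determinant correction that forbids reflections) on a fixed 18-atom
subset: backbone N/Cα/C of the five residues, Cys Sγ, the His binding
nitrogen, and the zinc. The exact subset used in the original survey was
published only in supplementary material not reproduced here; this
reconstruction spans the backbone conformation, both coordinating side
chains and the metal, is declared in every output, and is configurable
(`AtomSubsetSpec`).

Clustering is the greedy neighbour-count algorithm of g_cluster: repeatedly
take the element with the most neighbours within the cutoff (0.4 Å
default), form a cluster of it and its neighbours, remove them, repeat.
All ties break toward the lowest input index — g_cluster's own internal
order-dependence is not reproducible, so a deterministic rule is
documented instead. Singleton clusters are reported as outliers.

## Occurrences and propensities

Counting runs over the deduplicated (unique-sequence) motif set.
Propensity(r, pos) = (count/total)/background(r). The bundled background is
the UniProtKB/Swiss-Prot average amino-acid composition, and its label is
carried in all outputs; published propensity tables computed against a
different (unpublished) background are therefore reproduced only
approximately (typically within ~10%), and the package makes no attempt to
tune the background to force agreement.

## Dimer reconstruction

From an observed pseudo-symmetric pair (two 5-residue Zn-binding segments
on one zinc whose coordinating residues share χ1 rotamer classes), the
best-fit rigid transform mapping segment B onto segment A is computed on
backbone + Cβ + coordinating atoms, its rotation is projected to the
nearest exact 180° rotation (same axis), the axis is translated through
the zinc, and chain B is replaced by the rotated copy of chain A. Pairs
whose superposition RMSD exceeds 2.5 Å are refused as not pseudo-symmetric.

From a single motif, a C2 homodimer is generated by a two-fold rotation
about an axis through the zinc chosen to make the completed 4-ligand set
{S, N, R(S), R(N)} most tetrahedral. This completion is intrinsically
degenerate — a near-tetrahedral ligand pair admits several two-fold axes,
half of each handedness — so the axis is selected by (1) a chirality
preference, defaulting to Λ for survey reconstructions because natural
CysxHisy dimers are universally Λ; (2) least inter-chain crowding;
(3) lowest tetrahedricity. Inter-chain heavy-atom contacts below 2.4 Å set
a clash flag but are not fatal: loose dimers are physically meaningful
here. Chain A atoms are never moved, so ligand–zinc distances are exactly
preserved in the copy.

### Rebuilding survey motifs from printed statistics

Crystal coordinates of the survey entries are not bundled; their motifs
are rebuilt from printed statistics. The published tables fix the six
central backbone torsions and both χ1 values but leave three variables
free, which are resolved from other published observables rather than
guessed:

* **ψ of the Cys residue** orients the entire turn relative to the Cys side
  chain and is solved by the zinc-closure optimization below;
* **His χ2** is constrained by the published intra-residue Hε1/HN distance
  of ~6 Å together with zinc closure; when two χ2 branches satisfy both,
  the branch admitting a sterically viable C2 dimer is kept (each entry
  hosts an actually observed dimer, so a branch whose every completion
  clashes cannot be native);
* **the Zn direction** from Sγ is a torsion about the Cβ–Sγ bond at a
  107° Cβ-Sγ-Zn angle.

These reconstructions carry idealization error of a few tenths of an Å in
derived distances: the 4ijd-based dimer reproduces its published
inter-chain Hε1→HN distance (5.95 vs 6.0 Å) while the 2au3-based dimer
comes out at 3.7 vs 4.4 Å. The topological discrimination — the 2au3
contact is short enough for an NOE, the 4ijd one is not — is robust.

## The synthetic-data generator

The peptide builder places atoms by internal coordinates (natural-extension
reference frame) with canonical bond lengths/angles, trans peptides and
L-configuration (Cβ improper +122.6°), so requested φ/ψ/χ torsions are
realized exactly before noise; a rotamer/fragment library is unnecessary
because the cluster separations (tens of degrees in χ1) dwarf idealization
error. Zinc is planted 2.34 Å from Sγ, and the His ring is oriented so Nδ1
sits 2.05 Å from the zinc along its in-plane lone pair, via a coarse-grid +
Nelder-Mead search over (ψ_i, Zn torsion, χ2).

The benchmark population reproduces the survey's shape: clusters of 86,
16, 13 and 11 members plus three singleton outliers (129 motifs), built at
the printed per-cluster mean torsions with 5° Gaussian torsion jitter and
0.05 Å coordinate noise, plus decoys that each violate one mining
criterion (non-coordinating zinc, His spacing ≠ 3, extended backbone).
Because the survey's clusters are *defined* by the 0.4 Å RMSD cutoff,
members are rejection-sampled to lie within 0.35 Å of their cluster's
reference build: uncorrelated torsion jitter alone would scatter members
beyond the cutoff the population emulates (real intra-cluster torsion
variation is correlated). What passing the recovery test shows, therefore,
is that mining + superposition + clustering faithfully recover a partition
of the survey's geometry and proportions — not that the pipeline would
reproduce the survey's counts on the live PDB, which depend on the
snapshot and identity culling of the original query.

Titration generators reproduce the experimental designs: direct titration
into 8.0×10⁻⁴ M peptide over 0–2.5 metal equivalents; competition
titration into 1.0×10⁻³ M peptide pre-loaded with 3.5 equivalents of
Co(II) over 0–6 equivalents of the competing metal; 18 points per curve;
Gaussian noise with σ = 0.02 on the saturation fraction; pH series from
3.8 to 9.2.

## Binding model

With n peptides per metal (default 2), the dissociation constant is kept
on the scale K_D = [M]f^(1/n)[P]f/[MPₙ]^(1/n), which has molar units and
makes published µM values directly comparable; equivalently [MP₂] =
[M]f[P]f²/K_D². Speciation reduces to one monotone mass-balance equation
in the free peptide concentration, solved by Brent bracketing on
(0, P_t] to machine precision; mass balances are audited to 10⁻⁹ relative
at every return. Competition introduces the exchange constant through
K_D² = K_D¹/√K_ex, and the solver verifies the K_ex identity on its own
output.

Fitting minimizes unweighted squared error in the saturation fraction —
nothing in the source design justifies weights — with K_D (and K_ex)
log-parameterized for positivity; n can be fitted continuously and is
reported rounded. Standard errors come from the Jacobian at the optimum.
Competition fits hold the directly determined K_D of the first metal
fixed. The pH transition uses a two-state sigmoid with a Hill slope, a
documented modelling assumption. Single-run estimates at the experimental
noise scatter by ~13% (the published Cd value itself carries 20%
uncertainty); the acceptance script therefore reports medians over 25
replicate titrations, while the tests also check single fixed-seed runs.

Absorbance-to-saturation conversion (molar-absorptivity scaling) is the
caller's responsibility throughout; the package's observable is
Y = n[MPₙ]/P_t.

## Peptide masses

Masses assemble from per-residue elemental formulas (residue = amino acid
− H₂O) plus one water, +C₂H₂O for N-acetylation and −OH+NH₂ for C-terminal
amidation, with IUPAC 2021 average atomic weights (monoisotopic masses use
the dominant isotopes). Aib (2-aminoisobutyric acid) is C₄H₇NO. The
undecapeptide Ac-CTGHSGN{Aib}SEI-NH₂ computes to 1130.2 amu average
(C₄₄H₇₁N₁₅O₁₈S), within 0.3 amu of the published calculated value; the
residual reflects rounding conventions in the published figure.

## Problem sizes and numerical choices

The benchmark runs at the survey's full size (129 motifs + 6 decoys);
building it takes ~2 minutes and the pipeline seconds. Dimer
reconstructions take ~15 s each, dominated by the χ2-branch search.
Equilibrium solves use brentq with xtol = 10⁻¹⁸·P_t; torsion builders are
exact to <0.01°; PDB serialization rounds coordinates to 3 decimals,
bounding round-trip torsion error well under the 0.5° the tests assert.

## Known limitations

* The pipeline cannot reproduce the survey's live-PDB counts (129 motifs /
  44 unique sequences) from the PDB itself without the original snapshot
  and 50%-identity culling; those numbers enter as reference data and as
  generator proportions.
* Survey-entry reconstructions are built from printed cluster-mean
  torsions, not per-entry coordinates; derived H–H distances carry a few
  tenths of an Å of idealization error (see the 2au3 figure above).
* The single-motif C2 completion cannot determine chirality from geometry
  alone (both handednesses always exist); the Λ label for reconstructions
  encodes the survey's empirical finding, and only the mirror-flip
  behaviour and the existence of a viable Λ completion are independent
  checks.
* The propensity background is a stand-in for an unpublished composition
  table; propensities agree only approximately.
* The peptide builder idealizes bond lengths/angles and truncates
  non-coordinating side chains at Cβ (Pro at Cδ); it is a fixture
  generator, not a model builder for simulation.
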