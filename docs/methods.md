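# Methods

## Cohorts and the chronological axis

The package compares two compound cohorts — natural products (NP) and
synthetic compounds (SC) — along a time axis derived from CAS Registry
Numbers. A CAS number `A-B-C` is treated as a registration-order key
`(A, B)`; the check digit `C` is the modulo-10 checksum of the digits of
`A` and `B` weighted 1.. from the right, and never participates in
ordering. Records with an invalid checksum are kept but flagged: a wrong
check digit usually means a typo, not a different registration epoch.
Each cohort is sorted by key (ties broken by record id for determinism) and
cut into fixed-size groups; the tail that cannot fill a complete group is
dropped rather than kept as a short group, so every group mean averages the
same number of molecules.

## Standardization

Multi-component inputs keep the fragment with the most heavy atoms (ties:
molecular weight, then canonical SMILES — a deterministic, if arbitrary,
final tie-break). Molecules are rejected if they contain elements outside
{H, B, C, N, O, F, Si, P, S, Cl, Br, I, Se}, contain no carbon, or fall
outside the inclusive 70–2000 Da window (the filter removes strictly-small
and strictly-large molecules, so boundary values stay). No charge
neutralization or tautomer canonicalization is applied: canonical isomeric
SMILES of the kept fragment is the identity key everywhere downstream, and
any further normalization would be a second, silent notion of identity.
Duplicate structures within a cohort are kept by default (flag-controlled):
registration databases do contain genuine re-registrations.

## Sugar removal

A candidate circular sugar is a ring that satisfies all of: size in {5, 6};
exactly one ring oxygen, all other ring atoms carbon; no aromatic ring bond;
isolated (shares no atom with another ring, which excludes fused and spiro
sugars by construction); and exocyclic-oxygen density ≥ 0.4, counting one
oxygen per ring atom it bonds to (keto and carboxyl oxygens included). No
O-glycosidic attachment is required — the detection pattern alone decides.

Removal deletes the ring atoms and those exocyclic oxygens whose heavy
neighbours all lie inside the deleted set. A bridging (glycosidic) oxygen
therefore survives on the aglycone side: salicin yields the full salicyl
alcohol skeleton, and methyl glucopyranoside yields methanol. Removal
iterates to fixpoint — stripping one sugar can expose another — keeping the
largest remaining fragment each round (non-terminal sugars can disconnect
the molecule, and the downstream statistics need one structure per record).
A molecule is `sugar_only` when nothing with a heavy atom remains; such
molecules leave the cohort. No molecular-weight refilter is applied to
aglycones. Linear (acyclic) sugars are not detected; this is a documented
limitation, acceptable because the cohort statistics key on ring sugars.

## Descriptor panel

34 fields: size (MW, heavy atoms, bonds), rings (count, assemblies,
aromatic/non-aromatic, size bins 3–8+), polarity (AlogP = Crippen
atomic-contribution logP; TPSA = Ertl fragment sum; log solubility = ESOL,
`logS = 0.16 − 0.63·clogP − 0.0062·MW + 0.066·RB − 0.74·AP`; Lipinski
HBA/HBD), complexity (potential stereocentres, assigned chiral centres,
stereo double bonds, sp³ carbons, rotatable bonds excluding amides), and
element counts (F, Cl, Br, I, N, O, S, P — "content" of an element means
mean atoms per molecule, matching count-scale axes). ESOL is the package's
declared solubility model; absolute values differ from proprietary models,
so trends across groups, not levels, are the testable object. logD is
deliberately absent: it requires pKa prediction, which is out of scope.

Shape descriptors come from one ETKDG conformer with a fixed seed (default
2016): volume by 0.2 Å grid integration over van-der-Waals spheres, surface
area by Shrake–Rupley, and globularity = λ_min/λ_max of the heavy-atom
gyration tensor, clamped to [0, 1] (0 = linear or planar, 1 = spherical).
Embedding failures leave the three fields absent and exclude the molecule
from those group means only. In the pipeline, shape is computed on a seeded
per-group subsample (default 25 molecules/group): group means are the
consumer, and a fixed-size subsample estimates them at a fraction of the
conformer-generation cost; the subsample size is a config knob.

## Fragment decompositions

Scaffold and side chains share one atom partition, so heavy atoms are
conserved exactly. Scaffold atoms are: ring atoms, non-ring atoms surviving
iterative pruning of terminal atoms (i.e. atoms on a path between two
rings), plus atoms multiply-bonded to either (exocyclic =O stays). Side
chains are the connected components of the complement, each with one dummy
attachment marker. Acyclic molecules have no scaffold, no assemblies, no
side chains — but still count in every denominator *M*. RDKit's own Murcko
implementation is used as an independent cross-check in the tests, never as
the implementation.

Ring assemblies merge rings sharing ≥ 1 atom (fused and spiro alike) and are
extracted with their ring bonds and exocyclic multiply-bonded atoms. Per
assembly the package reports ring count, aromatic ring count, spiro atoms
(shared by exactly two rings joined at one atom) and bridgehead atoms
(≥ 3 ring bonds, not spiro).

RECAP fragments are the leaves of an exhaustive decomposition over the
eleven published retrosynthetic bond classes (amide, ester, amine, urea,
ether, olefin, quaternary N, aromatic N–aliphatic C, lactam N–aliphatic C,
biaryl, sulfonamide), via RDKit's implementation. "More than three heavy
atoms" is implemented as `min_heavy = 4`; attachment markers never count.
Fragment identity everywhere is canonical isomeric SMILES with generic
(unnumbered) markers, so equivalent fragments from different molecules
merge. All fragments passing the size filter are kept, ring-bearing or not.

## Diversity statistics

Per group and fragment type: abundance = N/M (N counts occurrences),
uniqueness = N_sing/M and novelty = N_novel/M (both count distinct types).
Occurrence-counting for N is forced by the observation that scaffold
abundance approaches 1 in cyclic-dominated cohorts, while type-counting for
novelty makes mean(novelty) = distinct types / (groups × M) an exact
identity the suite asserts. Singleton status is decided within the
fragment's own cohort over grouped molecules only; a flag switches to a
joint NP+SC universe. Novelty is order-dependent by construction and uses
the chronological group order.

The ring-assembly catalog counts per-cohort frequencies over all analyzed
molecules, filters per cohort at frequency > 5 (an assembly can survive in
one cohort only; surviving entries keep both raw counts), and assigns four
categories: NP-unique, SC-unique, and common split by whichever cohort's
earliest carrier CAS key is smaller.

## Biorelevance

NP-likeness is retrained, not imported: circular atom environments of radius
≤ 2 are counted over the NP and SC training corpora, and each environment
contributes `log10(((c_NP+1)/T_NP) / ((c_SC+1)/T_SC))` (Laplace smoothing
keeps every contribution finite; environments absent from both corpora
contribute 0). A molecule scores the sum over its environments divided by
heavy-atom count, clipped to ±5. Swapping the corpora negates every score
exactly. Absolute parity with externally trained scorers is explicitly not a
goal; the per-group trend direction is the testable object. The BR score is
the maximum Tanimoto similarity of a radius-2/2048-bit circular fingerprint
to a config-supplied reference set; the fingerprint choice is declared, not
inferred from any upstream source.

## Chemical-space maps

PCA (property and fingerprint) z-scores columns, drops constant columns with
a relative tolerance, and fixes signs by making each component's
largest-magnitude loading positive — coordinates are then invariant to row
order and run order. The tree map computes exact pairwise Jaccard distances
and an exact Kruskal MST with lexicographic (weight, i, j) tie-break; an
LSH-approximate neighbour layer is unnecessary at desk scale (a 50,000-node
bound guards the quadratic cost). Layout is a seeded force-directed
placement of the tree. The nonlinear map is classical (Torgerson) metric
MDS via eigendecomposition — deterministic, and exact on Euclidean-embeddable
distances, which the tests exploit (1-D line recovery within 1%). Points
carry the four catalog categories as colors and frequency as size.

## Synthetic cohort generator

The generator is the package's stand-in for the unavailable commercial
collections, and its defaults are the study conditions: 5000 molecules per
cohort in 10 chronological groups of 500, seed 2016. NP-like molecules are
assembled from fused/spiro/bridged aliphatic cores (decalin, hydrindane,
spiro[4.5]decane, norbornane, bicyclo[2.2.2]octane, tri- and tetracyclic
frames) decorated with O-rich substituents, random stereocentre assignment,
and pyranose units attached through an oxygen at glycosylation fraction 0.16
(the reported share of glycosylated natural products), with 1 + Poisson(0.5)
sugars per glycoside (mean 1.5). The per-group target MW drifts +6 Da/group
from a 280 Da base, emulating the historical upward drift of NP size.
SC-like molecules are aromatic monocycles (benzene, azines, thiophene,
furan; aromatic bias 0.9) joined by amide/amine/sulfonamide/ether/biaryl
linkers, halogenated with per-site probability 0.35, within a drug-like
size window. Pseudo-CAS numbers are allocated strictly increasing and
interleaved between cohorts, always with valid check digits, so cross-cohort
first-occurrence categories are meaningful.

What the generator does *not* emulate: real reaction chemistry or
synthesizability, linear sugars, tautomer/charge diversity, scaffold
popularity dynamics (fashion effects), or the heavy-tailed redundancy of
real registration data. Passing tests therefore demonstrate that the
*pipeline* recovers programmed signals (glycosylation fraction within
binomial error, MW rank-correlation > 0.9, NP/SC likeness separation,
aromatic/non-aromatic ring contrast) — not that real collections show those
signals.

## Numerical choices and degenerate inputs

Group size, RECAP floor, catalog frequency floor, deglyco threshold and
conformer seed are config knobs recorded in the run manifest. Unparsable
structures and missing CAS numbers become counted outcomes, never
exceptions. A group with all values missing yields an absent mean, flagged.
All-constant PCA input and sub-2-node tree maps are errors; an all-zero
distance matrix embeds to a single flagged point. Test and acceptance
problem sizes (200–5000 molecules per cohort, 10 groups) were chosen as the
smallest scales at which the binomial and rank-correlation assertions have
comfortable margins.

## Known limitations

- CAS order is a proxy for time; no calendar-year mapping is attempted.
- Aglycone identity is not stereo-aware (glucose vs galactose merge).
- The descriptor panel is the 34-field named set, extensible via config;
  no claim of numerical parity with proprietary descriptor engines.
- The greedy nearest-CAS SC subsampling stage is greedy, not globally
  optimal, and is off by default.
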