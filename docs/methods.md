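# Methods

## Scope and model

`trajnet` analyzes a conformer ensemble of a (multi-chain) protein/nucleic
complex — a set of structures sharing one atom topology — and summarizes its
collective dynamics as a network of *dynamic communities*: groups of residues
whose positional fluctuations are mutually correlated and spatially in
contact. Around that core it provides the supporting measurements such
analyses are typically reported with: per-residue flexibility (B-factors),
classified persistent contacts, minimum-energy paths between conformations
(nudged elastic band), and interface geometry (buried surface fractions,
duplex kink angles, lysine-reach scans).

The intended input is an ensemble sampled by molecular dynamics; the package
itself never runs dynamics. Frames are treated as exchangeable samples of a
conformational distribution — no time-correlation information is used
anywhere, which is why the synthetic generator's i.i.d. frames are an
adequate stand-in for testing every stage.

## Dynamic community networks

**Nodes.** One node per polymer residue, represented by its Cα atom (amino
acids) or P atom (nucleotides). Residues lacking the representative atom
(5′-terminal nucleotides) are skipped with a warning.

**Superposition.** Frames are rigid-body superposed (Kabsch, no scaling) on
the representative atoms, by default onto the ensemble mean with two
mean-reference iterations. Fewer than three non-collinear fit atoms leave
the rotation under-determined and are rejected.

**Correlations.** The linear dynamic cross-correlation (DCCM) estimator

    c_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

with Δr the displacement of the representative atom from its ensemble mean.
The signed linear estimator is used rather than a generalized or
mutual-information correlation: the downstream edge weight takes |c|, which
presumes a signed coefficient. Static (zero-variance) nodes would make the
quotient undefined; their rows are zeroed off-diagonal (diagonal 1) with a
warning so a frozen bead cannot poison the matrix.

**Contacts.** A residue pair is in contact in a frame when the minimum
distance between their heavy atoms is ≤ 4.5 Å (for bead models the beads are
the heavy atoms). Hydrogens are excluded from every distance test. Pairs
adjacent in sequence on the same chain (|Δresnum| ≤ 1) are excluded;
inter-chain pairs never are. An edge requires contact in at least 75% of
frames — the boundary is inclusive, read literally from the convention the
pipeline follows ("at least 75%"), and tested at exactly 0.75 vs 0.749.

**Edge weights.** w_ij = −ln(max(|c_ij|, ε)) with ε = 1e−6, so strong
correlation means a short edge; the floor caps w at ≈ 13.8155 and is logged
when hit.

**Communities.** Girvan–Newman: repeatedly remove the edge with the highest
edge betweenness (Brandes accumulation, each unordered pair counted once),
recomputing betweenness after every removal, until no edges remain. Ties are
broken toward the lexicographically smallest (i, j) pair, making the
procedure deterministic. After each removal the connected components of the
residual graph are recorded together with their Newman modularity

    Q = Σ_k (e_kk − a_k²)

evaluated on the *original unweighted* contact graph. The partition returned
is the global maximum of Q over the whole removal trace (earliest step on
ties); the full Q-trace is exported so the modularity plateau can be
inspected directly. Two open conventions had to be fixed: betweenness for
edge removal uses *weighted* shortest paths (w as length) by default, in
line with the dynamical-network-analysis lineage, while modularity is always
computed unweighted; both flags are recorded in the partition metadata and
the run manifest, and the unweighted-betweenness mode is available
throughout.

**Community graph.** One node per community (sized by member count); the
edge weight between two communities is the cumulative betweenness of the
original network's inter-community edges — a coarse-grained map of where
dynamic communication concentrates.

**Convergence.** The whole pipeline is run independently on the first and
second halves of the frames and the two partitions are compared by the
adjusted Rand index, together with per-half Q and community counts.

## Flexibility

MSF_i = ⟨|r_i − ⟨r_i⟩|²⟩ over superposed frames; B_i = (8π²/3)·MSF_i
(≈ 26.32 Å² at MSF = 1 Å²). B-factors are written back into PDB files
(%6.2f, clamped to [0, 999.99] with a warning; unkeyed residues get 0.00) so
flexibility can be rendered on the structure.

## Persistent-contact classification

For interaction reporting, tighter per-class conventions are applied to
full-atom models: an inter-residue N/O–N/O atom pair at ≤ 3.5 Å counts as a
hydrogen-bond/salt-bridge event, an apolar C–C pair at ≤ 4.5 Å as a
hydrophobic event. A contact is persistent when its event fraction exceeds
0.60 *strictly* ("more than 60%"; 0.60 exactly is excluded — tested).
Donor/acceptor typing is deliberately operational: N/O proximity, with no
angular criterion. Apolar carbons are identified by name heuristics
(backbone C/Cα and the carbons bonded to N/O in charged/polar side chains
are excluded); this is a stated approximation, not a perceived bond graph.

## Synthetic ensembles with planted structure

The generator builds ground-truth-labelled ensembles whose statistics and
geometry mirror what the pipeline assumes about real trajectories:

* **Topology.** Each block is one chain of Cα/P beads on a 3-D lattice with
  4.0 Å nearest-neighbour spacing — safely inside the 4.5 Å cutoff. Lattice
  box dimensions are chosen by maximizing the filled lattice's adjacency
  (the most compact, edge-dense shape), which keeps each block's contact
  graph cohesive enough that its best-modularity split is no split.
  Consecutive blocks are joined by a declared number of bridge bead pairs
  4.0 Å apart, protruding from the block faces with 8 Å lateral spacing;
  every non-bridge inter-block pair is > 6 Å away, verified exhaustively at
  build time. Residues are numbered in lattice-parity (checkerboard) order
  so the |Δresnum| ≤ 1 exclusion never severs a lattice contact.
* **Displacements.** Zero-mean Gaussian, applied identically and
  independently per Cartesian axis, with node-pair correlation
  `intra_corr` within blocks and `inter_corr` across — an equicorrelated
  block model, the simplest structure whose positive semi-definiteness is
  easy to certify (and is re-certified numerically before sampling; the
  failure message names the offending parameters). A single integer seed
  drives one generator; identical (spec, seed) gives bit-identical frames.
* **Defaults** are the study conditions used throughout the tests:
  intra_corr 0.8, inter_corr 0.1, fluct_sigma 0.3 Å per coordinate,
  5000 frames, 1 bridge per consecutive block pair. σ = 0.3 Å keeps the
  4.0 Å contacts and > 6 Å separations robustly on either side of the
  4.5 Å cutoff; real ensembles' fluctuation magnitudes are system-specific,
  so this is a convention, not a fit.

What the generator does *not* emulate: force-field energetics, solvent,
anisotropic or time-correlated motion, rigid-body drift between frames, and
side-chain atoms. Passing the planted-recovery tests therefore demonstrates
the statistical and graph machinery end-to-end — estimator consistency,
contact filtering, weighting, community detection — but not robustness to
force-field artefacts or sampling autocorrelation in real trajectories.

Note that superposition removes the ensemble's common-mode displacement, so
the *apparent* correlations after alignment are systematically lower than
the planted values (≈ 0.3 after alignment for a planted 0.8 with these
block sizes). This mirrors real practice — correlations are always defined
relative to an alignment — and does not affect recovery, since the contrast
between intra- and inter-block correlation survives. Estimator-recovery
checks are run on unaligned frames, where the planted values are the truth.

## Nudged elastic band

A band of R replicas connects two fixed endpoints; interior replicas feel
the potential force projected perpendicular to the local tangent plus a
spring term k(|d_{i+1}| − |d_{i−1}|) along it, with the improved
(uphill-neighbour) tangent of Henkelman & Jónsson to suppress kinks. A
partial band restricts tangent and spring to a masked coordinate subset;
unmasked coordinates feel the bare potential force and simply relax.

Optimization is deterministic FIRE-quenched steepest descent (steps clamped
to `max_step`), not thermally annealed dynamics — thermal sampling adds
nothing on desk-scale analytic surfaces and would break reproducibility.
Convergence requires the maximum per-replica displacement to stay below
`tol` for ten consecutive iterations, because FIRE takes a spuriously tiny
step right after each velocity reset. Non-convergence flags the result
rather than raising. A climbing image (off by default) is enabled after the
plain band has relaxed and drives the highest replica to the saddle; the
Müller–Brown benchmark (R = 16, k = 0.1, climbing on) places it within
10⁻³ of the saddle found by a 2000×2000 brute-force grid bottleneck search.
Two degenerate regimes are handled explicitly: identical endpoints switch
the band to a plain (unprojected) elastic band, since with tangent
projection any collinear spike is an equilibrium; and the per-replica
residual force on kinked surfaces has a discretization floor set by R, so
force thresholds are meaningful only relative to the initial band forces.

The default spring constant for molecular-scale (Å, kcal/mol) coordinates
is 10 kcal mol⁻¹ Å⁻²; analytic benchmark surfaces use the k the caller
passes (0.1 for Müller–Brown, matching its much larger energy scale).

## Geometry

* **SASA.** Shrake–Rupley with a deterministic Fibonacci-spiral point set
  (960 points/atom), probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 /
  P 1.80 / H 1.20 / other 1.70 Å. A single atom reproduces 4π(r+probe)²
  exactly by construction; two-atom configurations agree with a
  100 000-point evaluation within 1%.
* **Buried fraction** of a component = (SASA alone − SASA in complex)/SASA
  alone, with a per-partner decomposition obtained by removing one partner
  chain at a time and normalizing the restored areas.
* **Duplex kink angle.** Each arm's axis is the first principal direction
  of its backbone P (fallback Cα) atoms, oriented away from the junction
  (the closest inter-arm residue pair); the reported angle is between the
  two away-pointing axes, so a straight duplex reads 180° and a 140° value
  means a 40° bend. The principal-direction proxy, not a fitted helical
  axis, is deliberate: it is exact on straight arms and rotation-invariant.
* **Lysine reach.** All LYS residues on target chains whose NZ (the
  chemically attacked amine; Cα fallback is flagged) lies *strictly* within
  the cutoff (default 12 Å) of a reference atom — per conformer and as an
  ensemble union with per-residue minimum distances.

## Numerical conventions

* Contact persistence boundaries: ≥ 0.75 inclusive, > 0.60 strict.
* Correlation floor ε = 1e−6; |c| clipped to [−1, 1]; matrices symmetrized
  against roundoff.
* Girvan–Newman tie-break: lexicographically smallest edge; best-Q tie:
  earliest step. Edgeless graphs: singleton partition, Q defined as 0,
  warned.
* Altloc resolution: highest occupancy, ties prefer altloc 'A'/blank.
* All randomness flows from explicit integer seeds; there is no hidden
  global RNG state. Pipeline manifests record parameters, convention flags
  and SHA-256 checksums of all outputs; identical config + inputs give
  identical checksums.

## Problem sizes used in the shipped checks

Planted-recovery runs use two blocks of 10 residues, 5000 frames and five
seeds (plus a 10 000-frame run for estimator recovery); these sizes give
estimator noise far below the planted contrast while keeping the whole
suite fast. The headline analyses this machinery is modelled on ran on
ensembles three orders of magnitude larger (thousands of residues,
microsecond trajectories); nothing in the implementation is specific to the
small sizes, but the shipped checks validate correctness, not scalability.

## Known limitations

* Modularity is evaluated unweighted; a weighted-modularity variant is not
  provided.
* No time-lagged correlations, PCA or normal modes; no Louvain/Leiden
  alternatives; no statistical significance for communities.
* Contact classification has no angular hydrogen-bond criterion and no
  π-stacking detection.
* The NEB module optimizes paths on pluggable analytic potentials; it does
  not couple to a molecular force field.
* mmCIF is not written; bonds are never inferred.
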