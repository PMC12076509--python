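# Methods

This note documents the conventions, parameter choices and limitations of
porphgeom's models, in the order the pipeline runs them.

## Reference geometry

All calibrations and mode definitions rest on one idealized planar D4h
metalloporphine. Its quarter-unit coordinates are the exact solution of the
planar closure problem for standard aromatic bond lengths — M–N 2.01 Å,
N–Cα 1.38 Å, Cα–Cβ 1.44 Å, Cβ–Cβ 1.35 Å, Cα–Cmeso 1.395 Å — with a 125°
Cα–Cmeso–Cα angle fixing the remaining degree of freedom. The solution was
obtained once by Newton iteration on those five constraints and frozen as
constants in `reference.py`; rotating the quarter through the four-fold
axis generates the 24-atom macrocycle (4 N, 8 Cα, 8 Cβ, 4 Cmeso).
Derived positions: Cα at radius 3.051 Å (φ = ±21.1° per pyrrole), Cβ at
4.277 Å (±9.1°), meso at 3.433 Å on the diagonals.

## Curation

Bond perception uses the covalent-radius criterion d ≤ 1.15 (rᵢ + rⱼ) with
the Cordero-type table shipped with gemmi; the scale is configurable. Bond
orders come from a shortest-bond-first valence heuristic; every filter that
"counts double bonds as one connection" therefore simply counts graph
neighbours. Formal charges default to zero (CIFs rarely carry them), so
electron parity depends on elemental composition alone — which is exactly
what makes the parity filter reject d⁹ copper-type complexes.

Two filters needed operational definitions the inputs do not supply:

* **Connected molecule.** A separate (unbonded) component whose atoms come
  within 1.8× the summed covalent radii of the porphyrin component is
  treated as a broken fragment of one molecule — semi-bonding contact
  distances signal disorder or parsing artifacts, while genuine counter
  molecules pack farther away. The factor 1.8 sits between the bonding
  cutoff (1.15) and typical van der Waals contact.
* **Central "metal".** Any atom bonded to all four pyrrole nitrogens
  qualifies; no element whitelist, so metalloid-centered porphyrins pass.

Disorder is resolved per disorder group: the group with the strictly
highest mean occupancy wins; occupancies equal within 1e-6 are a tie and
the structure is rejected (a verdict, not an exception). CIF models are
symmetry-expanded: atom images over all symmetry operators and ±1 lattice
translations are grown outward from the asymmetric unit along bonds, so
molecules straddling the cell boundary come out whole; each asymmetric-unit
site is kept in exactly one component.

Hydrogens absent from an input file are never added during curation; the
saturation filter counts whatever connections are declared.

## Macrocycle detection and canonical labeling

Detection is purely topological: pyrrole candidates are 5-rings with one N,
meso bridges are carbons joining α-carbons of two different pyrroles, and a
porphine skeleton is a 4-cycle of pyrroles with four distinct bridges.
Distorted macrocycles are therefore found unchanged; corrole-like skeletons
(a direct pyrrole–pyrrole bond) are not matched. Ring positions are
canonicalized over the 8 symmetry images (4 rotations × reflection) by the
lexicographically smallest substitution-pattern encoding, with remaining
ties broken by atom index — harmless, because all descriptors are means
over positions. Substituent identity is the molecular-formula string plus a
Weisfeiler–Lehman hash of the substituent's element-labeled bond graph.

## HOMA calibration

The score of a circuit is HOMA = 1 − EN − GEO with α = 257.7 Å⁻². A planar
unsubstituted porphyrin cannot score 1 on every circuit under any single
(α, R_opt): the pyrrole circuits of the reference mix three bond lengths,
so their alternation term is strictly positive. The default calibration
(`class_anchor`) therefore anchors, per circuit type and bond class, R_opt
to the reference circuit's class-mean bond length: all deviations vanish on
the reference, the inner circuit scores exactly 1, and the pyrroles score
0.722 with GEO dominant — matching the observation that pyrroles are the
less aromatic subsystems of metalated porphyrins, with alternation as the
dominant penalty. The alternative (`baseline_shift`) uses the literature
R_opt(CC) = 1.388 Å with C–N lengths mapped onto the CC scale through
Pauling bond numbers (single/double lengths 1.467/1.349 Å for CC,
1.465/1.269 Å for CN) and subtracts the reference's raw EN and GEO as a
baseline; this preserves the identity HOMA = 1 − EN − GEO exactly, which a
multiplicative rescaling would not. Scores are not clamped to [0, 1]:
strongly stretched synthetic geometries legitimately go negative, and
clamping would hide calibration errors; out-of-range values are logged.

## NSD conventions

The six out-of-plane modes are built from geometric seed patterns on the
reference: alternating rigid pyrrole tilts about in-plane axes through the
nitrogens (saddling — β carbons move most, meso stays), alternating rigid
pyrrole twists about the M–N axes with the meso amplitude from smooth
angular continuation of the twist pattern (ruffling — meso : α : β
displacements 1.64 : 1.10 : 0.68, N fixed), an orbit-weighted
pyramidalization (doming — N 1.0, Cα 0.4, Cβ 0.1, Cmeso 0.25 before mean
removal), orbit-weighted differential tilts (waving x/y), and a same-sense
pyrrole twist (propellering). Seeds are purged of rigid-body content (net
translation and the two tilts) and Gram–Schmidt orthonormalized; by D4h
symmetry the cross-mode corrections are numerically negligible, so the
labels are clean.

Decomposition rigidly superposes the 24 slot-ordered atoms onto the
reference (centroid shift plus Kabsch rotation under the canonical
correspondence) and reads off the z coordinates; because every mode vector
is orthogonal to the rigid space, impose → decompose recovers any amplitude
vector to machine precision and the result is exactly invariant under
rigid motion of the input. A plane-fit route (the N4 or 24-atom
least-squares plane, provided as `fit_reference_plane` for reporting)
would mix in-plane coordinates into z once the fitted plane tilts and
cannot satisfy that exactness. Amplitude signs follow the canonical
labeling; when a metal is present the normal is oriented toward its axial
hemisphere, and absolute values are what downstream analyses consume. The
total out-of-plane value is the Euclidean norm of the out-of-plane
displacement vector; dividing by 24 gives the mean per-atom deviation
(0.6 Å ↔ 0.025 Å), a documented convention.

## Steric descriptors

Cone angles: the half-angle of the minimal enclosing cone is
min over axes u of max over atoms of [angle(u, vᵢ) + arcsin(rᵢ/‖vᵢ‖)],
solved by a deterministic 512-point Fibonacci-sphere scan with Nelder–Mead
polishing of the best candidates; a dense-grid oracle is kept for testing
(agreement within 0.5° on small fixtures; the single-sphere closed form
2·arcsin(r/d) is exact). The apex is the ring attachment atom for beta/meso
groups and the metal for axial ligands. Radii default to the covalent
table rather than van der Waals: with the apex one bond away, the vdW
sphere of the directly bonded atom (r ≈ 1.5–1.9 Å at bond lengths of
1.1–1.7 Å) engulfs the apex and no finite enclosing cone exists — the
covalent table keeps the descriptor well defined for every substituent,
hydrogen included, while preserving the bulk ordering
(H 33° < Me 75° < Ph 118° < tBu 132°). Bondi-type vdW radii remain
available for metal-apex cones where distances are large enough.

Surrogate distances: substituents are rigidly transplanted (apex onto the
site, the apex→first-atom bond onto the site's ideal direction, minimal
rotation, crystal conformation kept) onto a fixed two-site frame — the two
β sites of one pyrrole, or a meso site and its nearest β — and the minimal
interatomic distance is taken, symmetrized over the two site assignments so
the descriptor is orderless. The frame reuses the idealized attachment
geometry but encodes nothing else about the macrocycle. Distances shrink
as bulk grows (H/H 2.56 Å > Me/Me 1.96 Å > tBu/tBu 1.29 Å on the β–β frame).

Feature vectors: coordination number is 4 plus the number of axial
ligands; four-coordinate structures carry −1 as their axial cone — an
intentional sentinel that couples the two features, as it does in any
representation with this convention. The distance variant averages over
the four same-pyrrole β–β pairs and the eight meso–β neighbour pairs of
the canonical layout.

## Models and evaluation

Features are z-scored on training statistics before LASSO so coefficient
magnitudes are comparable across features (heatmap-ready); rescaling a raw
feature provably leaves the standardized coefficients unchanged. The
regularization grid is 50 logarithmic points from the smallest
all-zeroing alpha down four decades, chosen by five-fold CV on MAE with
seeded shuffling. Random forests (200 trees) provide the nonlinear
cross-check, interpreted by permutation importance. Bootstrap evaluation
re-draws the unseen-substituent split with a derived seed per replicate
(10 replicates, percentile 95% intervals); row resampling over a fixed
split is available as an option. The splitter moves whole substituent-
identity carrier groups to the test side, so chosen identities never occur
in training, and verifies the predicate exhaustively; when no combination
of groups reaches the requested test size exactly, the largest achievable
test set is used and logged. Models predicting the HOMA targets are
excluded from coefficient interpretation by default — their error is too
large relative to the score's range for the coefficients to mean much —
but an override includes them.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a curated crystallographic
population: metal distribution skewed to lighter d-block elements,
coordination numbers 4/5/6 (~33/42/25%), substitution patterns dominated
by meso-tetra (55%), then β-octa, fully substituted, and sparse patterns,
with substituent kinds drawn from a bulk-spanning library (H, halides,
methyl, ethyl, phenyl, tert-butyl; axial H₂O, NH₃, PH₃, pyridine, NMe₃,
PMe₃). Metals are even-Z and ligands even-electron so every generated
complex passes the parity filter, as curated sets do. Saddling and
ruffling amplitudes are planted as a linear law in the standardized
cone-variant features — bulk increases distortion; metal radius,
coordination number and axial bulk decrease it, with ruffling weighted
toward the metal/axial terms and saddling toward the macrocycle terms —
plus Gaussian noise whose SD is set so the linear signal explains ~70% of
the amplitude variance (σ = sd(Xβ)·√(3/7)); amplitudes are clipped at
zero. Geometries are then built by imposing those amplitudes, so
re-measuring the structures reproduces the targets; with σ = 0 the
round-trip is exact to 1e-8. Draws whose substituents would sterically
fuse (e.g. meso-tert-butyl beside substituted betas) are redrawn — the
population is conditioned on being curation-clean, as a curated set is by
definition.

Distorted geometries displace macrocycle atoms along the plane normal with
in-plane coordinates fixed; substituents translate rigidly with their
attachment atom. Bonds therefore elongate purely geometrically
(R′ = √(R² + Δz²)) with no force-field relaxation. This is the minimal
construction in which nonplanarity feeds back into bond lengths, and it is
deliberate: it makes every scan exactly reproducible and parameter-free.
Its cost is realism at large amplitude — real nonplanar porphyrins
accommodate distortion mostly through angle changes, keeping bond lengths
nearly constant, so the rigid construction overstates the EN (elongation)
penalty. Consequences visible in the scans: pure saddling lowers pyrrole
aromaticity monotonically and inner aromaticity slightly; pure ruffling
*raises* the mean pyrrole score (the short Cβ–Cβ bond elongates fastest,
killing the alternation penalty) before elongation takes over — but the
maximum falls at a total out-of-plane of 1.0 Å in this construction,
earlier than the ~2 Å seen in relaxed experimental structures. Pushing the
maximum outward would require either a force field or an unphysical
ruffling eigenvector (meso : α ≳ 4 : 1); both were rejected, and the
scan location is reported as computed. Passing tests on synthetic
populations demonstrate internal consistency and parameter recovery, not
agreement with crystallographic bond-length systematics.

## Numerical choices and degenerate inputs

Orthonormality and rigid-freedom of the NSD basis hold to 1e-10; the
energy partition Σ amplitude² + residual² = ‖z‖² is exact by construction.
Disorder ties use a 1e-6 occupancy tolerance. Plane fits reject collinear
point sets. Cone angles reject atoms whose sphere contains the apex
(r ≥ d) — the enclosing cone does not exist — and substituents with an
atom coincident with the apex. Empty circuits and circuit bonds missing
from the structure raise typed errors. Canonicalization ties on fully
symmetric patterns resolve by atom index. All stochastic steps (splits,
CV folds, bootstrap, population draws) take explicit seeds; derived seeds
come from a seeded generator and stay below 2³¹.

## Known limitations

* Bond perception is single-cutoff; haptic or very long dative bonds can be
  missed, and unusually short contacts spuriously bonded.
* The minimal NSD basis carries one vector per symmetry; extended
  multi-vector bases are out of scope, and mode amplitudes are not
  expected to agree bit-for-bit with other NSD implementations.
* The rigid z-displacement construction (above) understates the amplitude
  at which ruffling stops helping pyrrole aromaticity.
* Electron counting assumes neutral species unless formal charges are
  supplied; oxidation-state assignment is out of scope.
* The surrogate frame's dimensions are the idealized attachment geometry;
  other reasonable frames would shift the distance descriptors by a
  constant without changing their ordering.
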