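# Methods

This note documents the models, numerical choices and limitations behind
`abgraft`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Numbering by template alignment

Kabat and IMGT position labels are assigned by global (Needleman–Wunsch)
alignment of the query against a curated *maximal* consensus template per
(scheme, chain class) — a deliberately deterministic, dependency-free
alternative to HMM-based numberers. The templates live in
`src/abgraft/data/numbering_schemes.json` (versioned; the version string is
carried on every `NumberedChain`). Design points:

- **Maximal templates.** The IMGT templates occupy all 128 positions
  (CDR1 = 27–38, CDR2 = 56–65, CDR3 = 105–117 at full length); the Kabat
  templates include the canonical insertion columns (H35A/B, H52A–C,
  H82A–C, H100A–E; L27A–F, L95A/B). Shorter real chains are handled as
  deletions against the template, never as ad-hoc insertions.
- **Position-specific gap costs.** Deleting a CDR column or a canonical
  insertion column is nearly free; deleting an ordinary framework column is
  expensive (12 score units); the conserved cysteines (IMGT 23/104, Kabat
  H22/H92, L23/L88) are effectively undeletable, and a residue other than
  cysteine at an anchor raises `UnnumberableError` naming the anchor.
  Terminal template columns are near-free to skip (semi-global alignment),
  so N/C-terminally truncated domains — V genes without a J segment —
  number cleanly.
- **Canonical gap columns.** Each IMGT framework carries designated
  *padding columns* (heavy: 10, 73, 81, 82; light: 73–75) that are cheap to
  leave empty. This pins framework gap placement to canonical spots
  regardless of point substitutions in the query; without it, gap placement
  near repetitive motifs would be content-dependent and unstable. The two
  schemes' consensus strings are derived from one master content per chain
  class, so a motif (e.g. the FR3 head that Kabat assigns to CDR-H2's tail)
  sits at equivalent columns in both templates — authoring them
  independently makes the aligner latch onto the wrong copy.
- **CDR fill rules.** After alignment, CDR residues are re-labelled from
  their count: IMGT fills ceil(L/2) positions from the span start and
  floor(L/2) from the end (N-terminal side gets the extra residue;
  reproduces the canonical IMGT occupancy for all three CDRs). Kabat
  anchors the positions after the insertion point from the span end and
  fills the rest from the start, with letter codes for overflow. IMGT CDR3
  overflow past 13 residues is labelled 111A, 111B, … — a total-ordered
  stand-in for IMGT's 111.1/112.1 dot notation.
- **Limits.** Chothia/Martin/AHo schemes and nucleotide input are out of
  scope. Sequences outside 90–140 residues are rejected. A genuine
  framework insertion (beyond the canonical points) is reported as
  unnumberable rather than guessed.

## Germline library and grafting

The bundled library holds one entry per gene named in the humanization
campaign it models (three human heavy, three human kappa, two murine),
**as synthetic stand-ins**: consensus-derived sequences carrying the
distinguishing framework residues the workflow turns on (heavy 71/78 as
Lys/Val in IGHV2-9 and IGHV2-26 versus Val/Phe in the IGHV4 genes; light
60/66 as Lys/Arg in the murine kappa versus Ser/Gly in the human ones),
regenerable via `scripts/make_germline_library.py`. They are not IMGT
database alleles — headers and the filename say so — and any real library
can be supplied as FASTA.

Framework identity is computed over framework positions present in both
chains (gaps excluded, CDRs excluded); ties break by more aligned positions
then gene name. Grafting takes FR1–FR3 from the acceptor, CDRs (under the
chosen definition) from the parental chain, and FR4 from the acceptor if
present, else from a curated human J-segment consensus per chain class
(V genes end before FR4). The assembled chimera is renumbered and the CDRs
verified to have survived intact. Panels are heavy-major with deterministic
`{prefix}H{i}L{j}` tags. Back-mutations check the expected current residue
and re-label nothing: a point substitution cannot move scheme positions.

## SASA, BSA, contacts

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å, Bondi radii from
`data/vdw_radii.json`) — reproducible to the bit and convergent to <0.5%
per residue on doubling the point count. Per-residue BSA uses the
side-alone-minus-complex convention (as PISA reports it), clamped at zero;
"framework fraction of interface BSA" is reported over the antibody side
with CDR/framework classes from a caller-supplied region annotation.

Contact typing is heavy-atom geometric, precedence salt_bridge > hbond >
hydrophobic > vdw, first match per pair:

| type | default criterion |
|---|---|
| salt bridge | oppositely charged side-chain group centroids ≤ 4.5 Å (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2; Asp OD1/OD2; Glu OE1/OE2), reported on the closest atom pair |
| hydrogen bond | donor–acceptor heavy atoms ≤ 3.5 Å; D–H…A angle ≥ 100° enforced only when explicit hydrogens exist |
| hydrophobic | apolar carbon–carbon ≤ 4.0 Å (side-chain carbons bonded only to C/H) |
| vdW | distance ≤ r₁ + r₂ + 0.5 Å |

All cutoffs sit in `ContactConfig` (YAML-overridable from the CLI); the
cited tools the convention follows publish no single numeric standard, so
the defaults follow common practice and are surfaced in reports. Altlocs
keep the highest-occupancy conformer; waters always, and hetero atoms by
default, are excluded (opt-in flag for ions). Implementation uses a k-d
tree for pair pruning; the test suite proves equivalence against an
all-pairs brute-force oracle on ≤500-atom fixtures.

## Superposition, RMSD, RMSF

Superposition is closed-form Kabsch (SVD with determinant correction;
collinear selections rejected). Per-residue RMSD is computed over mapped
atoms (Cα by default) after fitting on a caller-chosen selection —
framework Cα in the humanization workflow, so CDR displacement is measured
in the scaffold frame. RMSF is `sqrt(mean_t |x_i(t) − x̄_i|²)` per selected
atom, with optional iterative superposition of each frame onto the
ensemble mean (default on, as for raw MD trajectories). Note that aligning
N atoms onto the mean absorbs ≈ 6/(3N) of isotropic variance, biasing RMSF
low by that fraction; the σ√3 calibration tests therefore use pre-aligned
ensembles (`align=False`), which is also the right setting for the
generator's jittered frames.

## Back-mutation proposal

A framework difference (parental vs humanized, same scheme, CDRs excluded)
becomes a proposal iff the parental residue has direct interface evidence —
BSA ≥ 10 Å² (config; chosen to separate emphasized interface residues from
incidental grazing contacts and surfaced in every report) or ≥ 1 typed
cross-interface contact — or sits in the Vernier zone. The bundled Vernier
table is the Foote & Winter (1992) position list (Kabat numbering), stored
as data with its citation. Proposals rank contact_and_vernier >
direct_contact (by BSA) > vernier. When a parental structure is supplied,
proposals whose Cβ (Cα for glycine) lie within 8 Å are cross-annotated as
coupled — generalizing the heavy 71/78 steric interplay without
hard-coding positions. Deliberately out of scope: ΔΔG prediction and
automatic acceptance; the proposal list is a ranked shortlist for a human.

## Binding kinetics

The 1:1 Langmuir model: association R(t) = R_max·C/(C+K_D)·(1−e^−(k_on·C+k_off)t),
dissociation R(t_a+τ) = R(t_a)·e^−k_off·τ. Fitting is `scipy`
Levenberg–Marquardt in log-parameter space (positivity for free), 10
multi-starts over a (k_on, k_off) grid, global mode sharing
k_on/k_off/R_max across the dilution series (per-trace mode for
diagnostics). Mass transport, drift and reference subtraction are outside
the model; lack-of-fit appears in the per-trace residual RMS. EC50 uses a
4PL with free Hill slope; a flat response raises a "no dose-dependence"
error rather than returning a meaningless EC50. The simulated assay
default mirrors the modelled experiment: a 7-point two-fold dilution from
125 nM, 180 s phases, 1 s sampling, k_on = 1e5 M⁻¹s⁻¹, k_off = 1.5e-4 s⁻¹
(K_D = 1.5 nM), with Gaussian response noise.

## Synthetic fixtures: what they do and do not show

Every generator emits machine-readable `GroundTruth` and is byte-stable
given (parameters, seed).

- **Sequences** derive from the bundled library plus the J consensus;
  substitutions (rate ≤ 0.1, C/W-free alphabet, never at anchors) and at
  most two CDR indels placed only where *both* schemes agree the position
  is CDR. Truth labels are maintained through the edits using the schemes'
  fill rules, so the 100-sequence cross-validation genuinely tests the
  aligner, not the fill rule in isolation.
- **Toy structures** are bead residues with real residue/atom names so the
  contact chemistry applies unmodified, written and re-read as valid PDB in
  the CLI path. The Fab-like complexes are *stand-ins* for crystal
  structures: identical buried atom pairs distributed so Kabat-framework
  residues carry 13 of 30 buried antibody atoms (≈43% framework BSA share,
  with L60/L66 doubled and hence strictly top), and the planted L-K60↔β-E65
  salt bridge and L-R66↔α-P81 main-chain H-bond at type-appropriate
  distances. The HCDR3 fixture displaces the loop beads up to 4.5 Å
  (loose graft) vs 0.225 Å (tight graft) under arbitrary rigid motions.
- **What passing does not show:** bead fixtures have no real protein
  packing, hydrogens, or crystallographic noise; sequence fixtures cover
  template-derived variation, not distant species or exotic CDR lengths;
  the kinetics generator is the same 1:1 model the fitter assumes, so
  recovery tests validate the estimator, not model adequacy for real
  sensorgrams with transport or drift. Analyses of real PDB complexes run
  through the same `read_structure` path but are not part of the bundled
  test evidence.

## Problem sizes

The default test and acceptance runs use: 100 synthetic sequences per
cross-validation, ≤ 120-atom toy complexes, 1000-frame ensembles of a
20-residue chain, 20 noise seeds for the KD recovery study and 12-point
titrations — sizes chosen so the whole suite completes in seconds while
keeping Monte-Carlo error well inside the asserted tolerances (e.g. the
σ√3 RMSF check at 1000 frames has ~1% sampling error against a 5% band).
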