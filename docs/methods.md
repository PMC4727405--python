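# Methods

## Data model

A cohort is a set of genes-by-samples tables joined only by sample
identifier: one numeric expression matrix (any non-negative unit; RPKM in
the typical case), up to four binary event tables (mutation, known-damaging
SNV, alternative splicing, indel — damaging status is assigned upstream by
the user, never inferred here), and one numeric copy-number table. No
table is mandatory; every downstream computation tolerates absent data
types by leaving the matching summary fields absent.

Missing versus zero is load-bearing in the flag tables: a blank cell means
*not assessed* and is excluded from frequency denominators, while 0 means
*assessed, event absent*. Conflating the two would silently deflate cohort
frequencies, so the TSV reader maps blanks to NaN and accepts only 0/1 and
case-insensitive true/false as assessed values; anything else is an error
with the offending gene and sample named.

Gene symbols are matched case-sensitively with no alias resolution; users
are expected to supply HUGO symbols consistently across tables and
pathways. Pathways are a small JSON dialect (nodes, directed/undirected
edges, family-node membership) chosen because it is self-describing and
round-trips exactly; families are materialized as ordinary nodes flagged
`is_family`, and a node may belong to at most one family.

## Cohort statistics

**Frequency and binning.** For gene g and data type t, frequency =
n_events / n_assessed over non-missing entries; undefined (absent) when
n_assessed = 0. Two thresholds 0 ≤ low_max < high_min ≤ 1 partition [0, 1]
into low / intermediate / high with the outer bins closed: f ≤ low_max is
low, f ≥ high_min is high. The closed-boundary rule is an arbitrary but
documented tie-break; with it the three bins partition [0, 1] exactly for
any valid threshold pair. Defaults low_max = 0.10, high_min = 0.30 are
plausible rare / infrequent / common cut-offs and are fully user-settable,
per data type if desired. One flat color per bin is used rather than a
within-bin gradient: it makes the color of a node a pure function of its
bin, which is testable and avoids implying precision a three-bin
classification does not have. Bin anchor colors are user parameters.

**Expression outliers.** Summary statistic is mean or median (default
mean). Sample s is an outlier for gene g iff |x_s − x̄_g| > k·s_g, with
s_g the sample (n−1) standard deviation over assessed samples; the gene is
flagged iff the outlier fraction is ≥ min_outlier_fraction and at least one
outlier exists. Defaults k = 2, min_outlier_fraction = 0.05. Two
consequences worth knowing. First, for a plain normal cohort the expected
fraction beyond 2 empirical sds is ≈ 4.3–4.6%, i.e. just below the 0.05
default — genes with perfectly unimodal expression will occasionally be
flagged by sampling noise; raise min_outlier_fraction to ~0.08 if that
matters. Second, for a two-point mixture with minority fraction p, the
minority mode sits √((1−p)/p) sds from the cohort mean: p = 0.1 gives
z = 3 (robustly flagged at k = 2), while p = 0.2 gives z = 2.0 exactly —
on the decision boundary, where flagging depends on the realized minority
count. The discrimination test in the suite therefore uses a 10% minority
mode. Fewer than two assessed values: summary returned, outlier assessment
skipped.

**Copy number.** Mean deviation = mean(copy number) − neutral over
non-missing samples, neutral defaulting to the absolute diploid count 2
(set 0 for log-ratio input). Direction is the exact sign of the mean
deviation in both display modes. Boolean display mode additionally records
whether *any* sample deviates from neutral by more than epsilon (default
0.5, i.e. half a copy); the constant-height substitution this mode implies
is applied at layout time, so the stored summary always carries the true
mean deviation and relative/boolean mode agree on direction by
construction.

**Gene-list restriction.** A selected gene list only sets `restricted_out`
on genes outside it — the scene then paints them with the no-data color —
and never alters numeric fields, so per-sample detail views stay complete.
Family nodes carry no summary of their own; their members are summarized
individually and shown when the family is expanded.

## Layout

Depth is the length of the shortest directed path from the root set
(in-degree 0 over directed edges, after folding family members into their
family node), by multi-source BFS. Shortest rather than longest path keeps
depth well-defined in cyclic pathways. A pathway with no in-degree-0 node
(a pure cycle) designates the lexicographically smallest node id as root;
nodes unreachable from every root are placed one ring beyond the deepest
reachable node. Undirected interaction edges are drawn but contribute
nothing to depth, which needs direction.

A node at depth d sits at radius d × ring_spacing (default 10 scene
units), nodes within a ring evenly spaced in angle starting at angle 0,
ordered alphabetically by label (input order available); a sole root sits
at the origin. When a pathway has several depth-0 roots they cannot all
occupy the origin, so every ring is pushed one level outward (ring index =
depth + 1) — the one departure from the radius = depth × spacing rule, made
so that distinct nodes never collide. The bundled random-pathway generator
emits single-root connected DAGs, for which the plain rule holds
everywhere.

CNV elevation sets z = mean deviation × height_scale (default 5 scene
units per copy) in relative mode, or ± height_scale as a constant flag in
boolean mode, and attaches a cone record tagged gain (red) or loss
(green). Expanding a family places its members on a circle of diameter
child_spread at family_plane_height above the family sphere; collapse
removes exactly what expand added, so the pair is an exact involution on
the layout.

## Scene graph and exports

The scene is an ordered list of typed primitives — spheres, edges,
expression bars, splicing annuli, CNV cones, guide rings, text labels —
each with position, size and RGB color. Conservation properties hold by
construction: one sphere and one name label per visible node, one line per
pathway edge whose (family-resolved) endpoints are visible, one bar per
gene with expression data when the expression layer is active, one annulus
per gene with splicing data when splicing is active, cones exactly
mirroring the layout's cone records when CNV is active, guide rings only
when enabled. Sphere color is the bin color of the selected node-coloring
data type (default mutation), the family color for family nodes, or the
no-data color for restricted/absent genes. Expression bar height is linear
in the summary value (configurable scale, capped) and the numeric value is
also emitted as label text, red when the outlier rule flags the gene, so a
reader never depends on 3D perspective to compare bars.

Canonical JSON export sorts keys and rounds floats to 9 decimals, making
the bytes a pure function of (pathway, dataset, config, view); the test
suite asserts byte identity across repeated runs. The interactive HTML
export embeds that JSON verbatim in a self-contained page with a small
canvas renderer (drag to rotate, wheel to zoom, no external scripts); the
static image export draws the same primitives with matplotlib's 3D axes at
a fixed camera. The JSON is the contract: any other 3D backend can consume
it without touching this package. The per-gene "detail view" is a pandas
DataFrame of every per-sample value for one gene, sortable by any column
(e.g. relative copy number), rather than an interactive widget.

## Synthetic data

The generator exists so the entire pipeline is exercisable with no
external data. Per gene: binary events are independent Bernoulli(p) draws
per sample; expression is normal noise around a baseline, optionally mixed
with a second mode at a given fraction (Bernoulli assignment), truncated
at zero; copy number is the neutral value with round(fraction × n) samples
shifted by a fixed magnitude (deterministic count, random assignment, so
the specified mean deviation is recovered exactly up to rounding). Random
pathways are single-root connected DAGs — each node gets at least one
parent among earlier nodes, plus density-controlled extra forward edges —
with optional family grouping of sink genes and an optional back edge for
cyclic cases. One seeded NumPy generator drives everything; identical
seeds give byte-identical TSVs, and the seed is recorded in scene
provenance.

What the generator does not emulate: correlation between data types within
a sample (real mutation and expression co-occur in biologically structured
ways), sample-level covariates or batch effects, heavy-tailed RPKM
distributions, and structured missingness. Passing tests therefore
demonstrate the statistical and geometric machinery on well-specified
inputs, not robustness to the pathologies of real cohorts.

Default simulation sizes in the test and acceptance runs — cohorts of
40–1000 samples, pathways of 5–50 nodes — are chosen to keep parameter
recovery within tight binomial error (n = 1000 for the recovery checks)
while keeping the whole suite fast; they are not limits of the
implementation.

## Numerical and degenerate-input choices

Frequencies of genes with zero assessed samples, expression of genes with
no values, and CNV of genes with no values are all *absent*, never 0 or an
error, and render with the no-data color. Zero-variance expression vectors
produce no outliers (|x − x̄| > k·0 is false for identical values).
Validation failures in readers name the offending gene/sample or node/edge.
Ring radii are exact to double precision; geometry tests use 1e-9
tolerances. Scene floats are rounded to 9 decimals at export only;
in-memory coordinates are full precision.

## Known limitations

Isoform identity is not represented — splicing is a per-gene binary flag.
No statistical testing between patient subgroups is included; the package
summarizes and displays, downstream inference is out of scope. No
force-directed ("hair-ball") layout mode. KEGG KGML is not parsed; the
native JSON dialect is the only pathway format. Gene symbol aliasing is
deliberately not attempted.
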