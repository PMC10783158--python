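# Methods

This note documents the audit model, the measurement choices that shape
its numbers, what the synthetic corpus does and does not emulate, and
the design decisions taken where more than one defensible option
existed.

## The audit model

A notebook's *method reproducibility* is operationalized as: re-execute
every code cell exactly once, in document order, in an environment
rebuilt from the repository's own dependency declarations, and compare
the fresh outputs with the outputs stored in the document. This is a
deliberately mechanical notion — it asks whether the documented
computation replays, not whether its scientific conclusion holds.
Consequences of the definition:

* **Only the first error counts.** Execution stops at the first raised
  exception; later cells may hide further errors, dependent or not.
* **Out-of-order authoring is not replayed.** Stored execution counts
  often show that the author ran cells repeatedly or out of order; the
  audit runs top-to-bottom once. Nondeterminism, dynamic data, and
  order-dependent state all surface as "finished with different
  results".
* **One label per notebook.** Classification is a total function with
  fixed precedence: unavailable repository → non-target language →
  install failure → timeout/exclusion → typed exception → diff verdict.
  Every downstream statistic is a query over these labels, guarded by
  the conservation invariants listed in the README.

## Stage-level choices

**Link normalization.** Recognized dialects: plain repository URLs,
`/blob/`, `/tree/`, `/raw/` deep paths, nbviewer hosts
(`nbviewer.org`, `nbviewer.jupyter.org`, `nbviewer.ipython.org`),
`raw.githubusercontent.com`, trailing `.git`, trailing slashes and URL
fragments, scheme-less `github.com/...` mentions. Owner-only links,
`*.github.io` pages and gists are classified as rejections — values,
not errors — since they identify no repository. Owner/repo case is
preserved as written, but deduplication folds case, matching the
hosting service's case-insensitive routing. Mentions are collected from
all text nodes and `xlink:href` attributes; each mention's enclosing
section tag is recorded so stricter section policies (e.g. excluding
reference lists) can be replayed later without re-mining.

**MeSH fields.** Top-level MeSH descriptors proxy research fields. The
descriptor → top-level mapping is an injected lookup (file-backed
table); a live SPARQL adapter can implement the same interface. Offline
article XML carries headings in a
`subj-group[@subj-group-type="mesh-heading"]` group, since efetch
article XML has no dedicated MeSH element.

**Harvest.** Default branch only, via shallow clone (`git` CLI) or a
copy-a-directory backend for offline corpora. Unreachable repositories
are recorded as unavailable, never raised. Hidden directories
(`.git`, `.ipynb_checkpoints`) and symlinked paths are excluded from
notebook enumeration; files above a 64 MiB cap are recorded unparsed.
Submodule contents are not fetched (shallow clone without submodule
init), so notebooks inside submodules are out of scope.

**Static profiling.** An *empty cell* is one whose source is empty or
whitespace-only, regardless of type. POSIX portability of a filename
stem means every character in `[A-Za-z0-9._-]` with no leading hyphen;
the historic 14-character limit is reported as a separate flag, not a
violation. Windows-disallowed means a reserved device name (`CON`,
`PRN`, `AUX`, `NUL`, `COM1–9`, `LPT1–9`) or any of `<>:"/\|?*`.
`Untitled*`, `*copy*`, `*test*` flags are case-insensitive substring
matches on the stem (except `Untitled`, which is a prefix match as the
kernel generates it). Import locality: a top-level module name is
*local* iff it resolves to a `*.py` file or a package directory
anywhere under the repository, or is a relative import; dotted names
are recorded in full (so `matplotlib.pyplot` is countable), locality
decided by the head segment. Notebook-shell directives (`%magics`,
`!shell`, trailing-`?` introspection) are stripped before any grammar
parse and kept in a separate record; `%load_ext X` is additionally
tallied as a load extension.

**Language detection.** The Markdown language detector is injectable.
The production default is a stopword-frequency heuristic over four
high-volume languages (en/fr/de/es) that returns "undetected" for text
under three words; tests use a deterministic stub so expected outputs
are exact. Detector-specific percentages from any particular production
detector are explicitly not a target: short, code-heavy Markdown makes
all detectors unreliable, and per-language shares mostly measure the
detector.

**Style audit.** The style engine enforces a conservative subset of
PEP 8 via the `tokenize`/`ast` modules and reports findings under the
standard pycodestyle codes (E225/E226/E227/E228 operator spacing, E231
separator spacing with the slice and single-element-tuple exemptions,
E262/E265/E266 comments, E401/E402 imports, E701/E702/E703 compound
statements, E741 ambiguous names). Conservative means: a finding is
emitted only where the rule unambiguously applies, so clean code yields
none. Import placement (E402) is judged across cells in document order
because a notebook's code cells jointly form one module. No findings
are suppressed (no ignore list).

**Environments.** Granularity is one environment per (repository,
interpreter minor version, declaration set) — declarations are
repository-level facts, and this avoids redundant builds; repositories
with no declarations share one bundle environment per interpreter
version. The declared interpreter version is honored at minor
precision; when absent, a policy default applies (shipped default:
3.11). The no-declaration fallback installs a named *distribution
bundle* configured in policy, not hardcoded. Backends implement
`create`/`install`: the venv backend used throughout builds virtual
environments and installs strictly from a local package index
(`--no-index --find-links`), so installs are offline-reproducible and a
missing distribution fails fast; a null backend records plans without
building; a conda-style manager can implement the same interface for
production. Environments are cached by a content key over
(interpreter, source, declaration paths, bundle) — one spec is never
built twice. Install failure is a recorded outcome with the last
diagnostic log lines, never a crash. Only one CPython is assumed
present at build time; the requested version is recorded alongside the
actual one so reruns are comparable.

**Execution.** The cell runner is a standard-library-only script
launched as a subprocess of the environment's interpreter, with the
notebook's directory as working directory and on the module path
(mirroring kernel behavior). It emulates the interactive shell: a
cell's trailing expression becomes an `execute_result`, stdout/stderr
become `stream` outputs, the first exception is recorded by its class
name from the raised object (the `ename` convention) and ends the run.
`IOError` aliases `OSError` in modern interpreters; the reported name
is kept verbatim and a canonical name is recorded alongside. The
per-notebook wall-clock timeout (production default 3600 s; 3–4 s in
the test corpus) kills the whole process group; the runner rewrites its
trace file after every cell, so a killed run still reports how far it
got. Notebooks that keep erroring without terminating are cut off by
the same timeout and labeled rather than dropped. A failure to even
start the interpreter is a distinct marker classified as *excluded*.

**Diffing.** Outputs are compared per code cell after normalization:
ANSI escapes stripped, per-line trailing whitespace ignored,
consecutive same-name stream chunks merged (kernels split streams
arbitrarily), image/PDF payloads compared by digest of the decoded
bytes. Masking of transient tokens (heap addresses, ISO timestamps) is
off by default and behind a flag. Execution-count mismatches and
workspace file changes (from before/after content-digest manifests of
the notebook's directory) are tallied separately.

**Identity policy.** `finished_identical` requires zero output-content
differences. Execution-count and file differences are recorded but do
not affect the verdict by default; `strict_counters` / `strict_files`
flags enable the stricter readings. Rationale: stored execution counts
reflect the author's interactive session and differ from a clean
top-to-bottom replay for almost every real notebook, so counter-strict
identity would empty the identical class; both policies are
implemented so the choice is explicit and replayable.

**Reporting.** Percentages are rendered with half-away-from-zero
rounding at the caller's precision (the convention that reproduces the
published figures, e.g. 9100/10388 → 87.6); zero denominators yield an
explicit "undefined". Per-code-cell execution time is reported under
both estimators — ratio of group means and mean of per-notebook ratios
— because they answer different questions and can diverge by severalfold
on skewed corpora; neither is privileged. Group sizes in the
finished-notebook comparison are cross-checked against the flow counts
at query time.

## The synthetic corpus

The forge emulates, deterministically from a seed: JATS articles with
repository links planted across sections and encodings (element
attributes and plain text); repository trees covering every declaration
combination including an unresolvable requirement set and a missing
repository; a local wheel index making "declared and installable" real
without network; and notebooks engineered per behavior label —
clean-deterministic (stored outputs produced by actually executing the
forged code once at forge time), clean-nondeterministic (cells draw
from a fresh entropy source at run time; their stored "original"
outputs are seeded forge values emulating an earlier run, keeping the
tree byte-stable per seed), one fixture per common exception class,
timeout (sleeping 5× the configured execution timeout, robust to
scheduler jitter), a foreign-kernel notebook that is censused but never
run, and a notebook with no language metadata. The default corpus is
~38 notebooks in 10 repositories, every label at least twice — sized so
the full offline pipeline (five environment builds, ~32 executions, two
timeout waits) completes in well under two minutes on one CPU.

What the forge does **not** emulate, hence what green round-trip tests
do not show about real corpora: deep transitive dependency trees and
version conflicts (the dominant real-world install failure mode), large
data files and network access inside notebooks, GPU/multicore code,
kernel crashes from native extensions, non-UTF-8 encodings, and
adversarially malformed documents beyond simple invalid JSON/schema.
The forge demonstrates that the machinery measures correctly, not that
any particular real-world rate will recur.

## Known limitations

* Only Python notebooks are executed; R/Julia notebooks are censused
  and labeled non-target, as are notebooks without standard language
  metadata.
* Comments inside code cells are not analyzed; Markdown volume is the
  only documentation proxy.
* Import statements are profiled but never used to install
  dependencies; an import-informed environment planner would be a
  natural extension behind the same planner interface.
* The diff cannot distinguish meaningful result changes from cosmetic
  ones (e.g. progress bars); transient masking mitigates but does not
  solve this.
* The store is single-writer SQLite by design; corpus-scale parallel
  execution would need an external queue in front of it.
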