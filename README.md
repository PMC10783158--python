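# nbaudit

Automated auditing of the computational reproducibility of Jupyter
notebooks linked from the biomedical literature.

Many articles indexed in PubMed Central point to GitHub repositories
containing Jupyter notebooks. `nbaudit` answers, at corpus scale, the
question *"if I re-run those notebooks today, what happens?"* It

1. **mines** full-text JATS XML for publication metadata and repository
   links (normalizing every link dialect — `/blob/` paths, nbviewer
   renderings, `raw.githubusercontent.com` files, `.git` suffixes — to
   the canonical `https://github.com/{owner}/{repo}` form),
2. **harvests** each linked repository (default branch only) and
   enumerates its notebooks,
3. **profiles** each notebook statically: cell census, kernel/language,
   Markdown documentation effort, filename portability, import graph
   (external vs repository-local modules), and PEP 8 style findings,
4. **rebuilds** an execution environment per repository from its
   declared dependencies (`requirements.txt`, `setup.py`, `Pipfile`),
   falling back to a configurable data-science distribution bundle,
5. **re-executes** every Python notebook once, top to bottom, with a
   wall-clock timeout, recording the first raised exception,
6. **diffs** the fresh outputs against the stored ones (ANSI and
   trailing-whitespace insensitive; images by payload digest), and
7. **classifies** each notebook into exactly one outcome:

```
repo_unavailable | not_target_language | install_failed |
exception(type) | timeout | excluded |
finished_different | finished_identical
```

All flow statistics derive from these labels under hard conservation
invariants:

```
attempted = install_failed + executed
executed  = exceptions + excluded + finished
finished  = finished_identical + finished_different
```

The headline summary statistic for finished notebooks is the
reproducibility ratio `different / (different + identical)` — lower is
better.

Because live mining depends on the historical state of two external
services, the package ships a seeded **synthetic corpus forge**
(`nbaudit.forge`): it generates JATS articles, repository trees, a local
package index with an installable wheel, and notebooks engineered to
land in every outcome class (clean-deterministic, clean-nondeterministic,
nine common exception types, timeout, foreign kernel, missing language
metadata, unresolvable requirements), together with a ground-truth
manifest. The whole pipeline is therefore testable offline, end to end.

## Worked example

```python
from pathlib import Path
from nbaudit.forge import MESH_TABLE, forge_corpus
from nbaudit.mesh import table_lookup
from nbaudit.envs import EnvironmentPolicy
from nbaudit.pipeline import PipelineConfig, run_pipeline
from nbaudit.store import CorpusStore

ws = Path("audit-demo").resolve()
manifest = forge_corpus(ws / "corpus", seed=1, timeout_sleep=20.0)
config = PipelineConfig(
    workspace=ws / "work",
    exec_timeout=4.0,
    policy=EnvironmentPolicy(distribution_bundle=("forgelib",)),
    package_index=str(ws / "corpus" / "index"),
    repo_sources=manifest.repo_sources(ws / "corpus"),
    mesh_lookup=table_lookup(MESH_TABLE),
)
store = CorpusStore(ws / "store.db")
flow = run_pipeline(ws / "corpus" / "articles", store, config)
print(flow)
```

prints (about a minute on one CPU, most of it building virtual
environments and waiting out the two timeout fixtures):

```
FlowCounts(articles=5, repos_linked=10, repos_available=9,
           repos_with_notebooks=9, notebooks_total=38,
           notebooks_target_language=34, notebooks_attempted=34,
           install_failed=2, executed=32, exceptions=18, excluded=2,
           finished=12, finished_identical=8, finished_different=4)
```

Reading: of 38 notebooks in 9 reachable repositories, 34 are Python;
2 sit in a repository whose declared dependencies cannot be installed;
of the 32 executed, 18 raise a typed exception (two of each engineered
class), 2 hit the timeout, 8 finish with byte-identical outputs and 4
finish with different outputs (their cells draw fresh entropy). Every
label matches the forge manifest's ground truth.

Aggregates come from `nbaudit.report`:

```python
from nbaudit.report import percentage, repro_ratio, round_half_away
percentage(5429, 15817, 2)              # -> '34.32'  (install failures)
percentage(9100, 10388, 1)              # -> '87.6'   (exceptions)
round_half_away(repro_ratio(324, 879), 2)   # -> 0.27
```

A `nbaudit` console script exposes the stages individually
(`mine`, `harvest`, `profile`, `run`, `report`, `forge`, `export`);
see `nbaudit --help`.

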