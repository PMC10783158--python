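"""Seeded forge for a fully labeled offline audit corpus.

The forge generates, deterministically from a seed, everything the
pipeline consumes in the wild: JATS article XML with repository links
planted in several dialects and sections, repository trees with every
combination of dependency declarations, a local package index holding
one tiny installable wheel (so "declared and installable" is testable
offline), and notebooks engineered to land in every reachable pipeline
outcome — clean-deterministic, clean-nondeterministic, one fixture per
common exception class, timeout, foreign kernel, missing language
metadata, and unresolvable requirements.

The accompanying :class:`ForgeManifest` is the ground truth for every
round-trip test: for each notebook it records the engineered behavior
and the outcome label the pipeline must recover.

Clean-deterministic notebooks embed stored outputs produced by actually
executing the generated code once at forge time.  Clean-nondeterministic
notebooks draw from a fresh entropy source at execution time; their
stored "original" outputs are drawn from the seeded forge RNG, emulating
a previous run, which keeps the forged tree byte-stable for a fixed
(config, seed) while guaranteeing that any re-execution differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import random
import subprocess
import sys
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Optional

from lxml import etree

from . import notebook
from .records import OutcomeLabel

FORGE_PACKAGE = "forgelib"
MISSING_PACKAGE = "nbaudit-definitely-missing-package-xyz"
MISSING_MODULE = "nbaudit_definitely_missing_module_xyz"


class Behavior(str, Enum):
    CLEAN_IDENTICAL = "clean_identical"
    CLEAN_DIFFERENT = "clean_different"
    EXC_MODULENOTFOUND = "exc_ModuleNotFoundError"
    EXC_FILENOTFOUND = "exc_FileNotFoundError"
    EXC_IMPORT = "exc_ImportError"
    EXC_NAME = "exc_NameError"
    EXC_IO = "exc_IOError"
    EXC_ATTRIBUTE = "exc_AttributeError"
    EXC_VALUE = "exc_ValueError"
    EXC_TYPE = "exc_TypeError"
    EXC_KEY = "exc_KeyError"
    TIMEOUT = "timeout"
    NON_TARGET_KERNEL = "non_target_kernel"
    UNKNOWN_LANGUAGE = "unknown_language"
    INSTALL_FAIL = "install_fail"


#: raised exception class per exc_* behavior: (raised name, canonical name)
EXCEPTION_NAMES = {
    Behavior.EXC_MODULENOTFOUND: ("ModuleNotFoundError", "ModuleNotFoundError"),
    Behavior.EXC_FILENOTFOUND: ("FileNotFoundError", "FileNotFoundError"),
    Behavior.EXC_IMPORT: ("ImportError", "ImportError"),
    Behavior.EXC_NAME: ("NameError", "NameError"),
    Behavior.EXC_IO: ("IOError", "OSError"),
    Behavior.EXC_ATTRIBUTE: ("AttributeError", "AttributeError"),
    Behavior.EXC_VALUE: ("ValueError", "ValueError"),
    Behavior.EXC_TYPE: ("TypeError", "TypeError"),
    Behavior.EXC_KEY: ("KeyError", "KeyError"),
}

EXPECTED_OUTCOME = {
    Behavior.CLEAN_IDENTICAL: OutcomeLabel.FINISHED_IDENTICAL,
    Behavior.CLEAN_DIFFERENT: OutcomeLabel.FINISHED_DIFFERENT,
    Behavior.TIMEOUT: OutcomeLabel.TIMEOUT,
    Behavior.NON_TARGET_KERNEL: OutcomeLabel.NOT_TARGET_LANGUAGE,
    Behavior.UNKNOWN_LANGUAGE: OutcomeLabel.NOT_TARGET_LANGUAGE,
    Behavior.INSTALL_FAIL: OutcomeLabel.INSTALL_FAILED,
    **{b: OutcomeLabel.EXCEPTION for b in EXCEPTION_NAMES},
}

_FAILING_CELLS = {
    Behavior.EXC_MODULENOTFOUND: f"import {MISSING_MODULE}\n",
    Behavior.EXC_FILENOTFOUND:
        "with open('no_such_data_file_xyz.csv') as fh:\n    fh.read()\n",
    Behavior.EXC_IMPORT: "from os import no_such_name_xyz\n",
    Behavior.EXC_NAME: "print(undefined_variable_xyz)\n",
    Behavior.EXC_IO: "raise IOError('synthetic input failure')\n",
    Behavior.EXC_ATTRIBUTE: "'text'.no_such_attribute_xyz()\n",
    Behavior.EXC_VALUE: "int('not a number')\n",
    Behavior.EXC_TYPE: "len(42)\n",
    Behavior.EXC_KEY: "lookup = {'a': 1}\nlookup['missing_key']\n",
}


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

@dataclass
class NotebookSpec:
    repo: str
    path: str
    behavior: Behavior
    expected_outcome: OutcomeLabel
    expected_exception: Optional[str]          # canonical class name
    raised_exception: Optional[str]            # name as written in the code
    code_cells: int
    markdown_cells: int
    raw_cells: int


@dataclass
class RepoSpec:
    slug: str
    owner: str
    name: str
    available: bool
    has_requirements: bool
    has_setup: bool
    has_pipfile: bool
    path: Optional[str]                        # relative to workspace

    @property
    def canonical_url(self) -> str:
        return f"https://github.com/{self.owner}/{self.name}"


@dataclass
class PlantedLink:
    repo: str
    dialect: str
    section: str
    raw: str


@dataclass
class ArticleSpec:
    pmc_id: str
    title: str
    journal_issn: str
    journal_title: str
    planted_links: list[PlantedLink]
    planted_rejections: list[dict[str, str]]
    mesh_terms: list[str]
    keywords: list[str]
    xml_path: str


@dataclass
class ForgeManifest:
    seed: int
    timeout_sleep: float
    articles: list[ArticleSpec]
    repos: list[RepoSpec]
    notebooks: list[NotebookSpec]

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, Enum):
                return obj.value
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))
        return json.dumps(dataclasses.asdict(self), indent=1,
                          sort_keys=True, default=default)

    def repo_sources(self, workspace: str | Path) -> dict[str, Optional[str]]:
        """canonical_url -> local tree path (None for unavailable repos)."""
        ws = Path(workspace)
        return {r.canonical_url: (str(ws / r.path) if r.path else None)
                for r in self.repos}

    def notebook_labels(self) -> dict[tuple[str, str], NotebookSpec]:
        index = {r.slug: r for r in self.repos}
        return {(index[nb.repo].canonical_url, nb.path): nb
                for nb in self.notebooks}


# --------------------------------------------------------------------------
# local package index
# --------------------------------------------------------------------------

_FORGELIB_SOURCE = '''\
"""Tiny arithmetic helper published to the forge's local package index."""

__version__ = "0.1.0"


def triple(x):
    return 3 * x


def checksum(values):
    return sum((i + 1) * v for i, v in enumerate(values))
'''


def publish_package(index_dir: str | Path) -> Path:
    """Build the forge's installable wheel into the local index.

    Also drops an importable source copy under ``<index>/src`` so that
    forge-time execution of notebooks importing the package works
    without any installation.  Returns the source directory.
    """
    index = Path(index_dir)
    index.mkdir(parents=True, exist_ok=True)
    src = index / "src"
    pkg = src / FORGE_PACKAGE
    pkg.mkdir(parents=True, exist_ok=True)
    (pkg / "__init__.py").write_text(_FORGELIB_SOURCE)

    version = "0.1.0"
    dist_info = f"{FORGE_PACKAGE}-{version}.dist-info"
    metadata = (f"Metadata-Version: 2.1\nName: {FORGE_PACKAGE}\n"
                f"Version: {version}\n")
    wheel_meta = ("Wheel-Version: 1.0\nGenerator: nbaudit-forge\n"
                  "Root-Is-Purelib: true\nTag: py3-none-any\n")
    wheel_path = index / f"{FORGE_PACKAGE}-{version}-py3-none-any.whl"
    entries = {
        f"{FORGE_PACKAGE}/__init__.py": _FORGELIB_SOURCE,
        f"{dist_info}/METADATA": metadata,
        f"{dist_info}/WHEEL": wheel_meta,
    }
    record_lines = []
    for name, content in entries.items():
        digest = hashlib.sha256(content.encode()).hexdigest()
        record_lines.append(f"{name},sha256={digest},{len(content.encode())}")
    record_lines.append(f"{dist_info}/RECORD,,")
    entries[f"{dist_info}/RECORD"] = "\n".join(record_lines) + "\n"
    with zipfile.ZipFile(wheel_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, content in entries.items():
            info = zipfile.ZipInfo(name, date_time=(2020, 1, 1, 0, 0, 0))
            zf.writestr(info, content)
    return src


# --------------------------------------------------------------------------
# notebooks
# --------------------------------------------------------------------------

_PY_METADATA = {
    "kernelspec": {"name": "python3", "display_name": "Python 3",
                   "language": "python"},
    "language_info": {"name": "python",
                      "version": "%d.%d.%d" % sys.version_info[:3]},
}
_R_METADATA = {
    "kernelspec": {"name": "ir", "display_name": "R", "language": "R"},
    "language_info": {"name": "R", "version": "4.3.0"},
}

_MD_HEADER = "# {title}\n\nA worked example forged for the audit corpus.\n"
_MD_BODY = ("## Notes\n\n"
            "The cells below compute a small deterministic summary.\n\n"
            "- inputs are generated in place\n"
            "- results are printed, not saved\n\n"
            "[project link](https://example.org/forge)\n")
_MD_FRENCH = ("Le traitement des données est décrit dans les sections "
              "suivantes et les résultats sont affichés plus bas.\n")


def _prelude_cells(rng: random.Random, uses_forgelib: bool) -> list[str]:
    k = rng.randint(5, 12)
    cells = [f"values = [n * n for n in range({k})]\n"
             "total = sum(values)\n",
             "print('total', total)\n"]
    if uses_forgelib:
        cells.insert(0, "import forgelib\n")
        cells.append("print('triple', forgelib.triple(total))\n")
    return cells


def forge_notebook(behavior: Behavior, *, name: str, rng: random.Random,
                   markdown_cells: int = 2, raw_cells: int = 0,
                   timeout_sleep: float = 25.0, uses_forgelib: bool = False,
                   uses_local_module: bool = False,
                   style_violations: bool = False,
                   writes_file: bool = False,
                   bilingual: bool = False) -> dict[str, Any]:
    """One engineered notebook document (stored outputs included)."""
    if behavior is Behavior.NON_TARGET_KERNEL:
        cells = [notebook.markdown_cell("# Analysis in R\n"),
                 notebook.code_cell('x <- c(1, 2, 3)\nprint(sum(x))\n')]
        return notebook.new_notebook(cells, dict(_R_METADATA))
    if behavior is Behavior.UNKNOWN_LANGUAGE:
        cells = [notebook.code_cell("print('hello')\n")]
        return notebook.new_notebook(cells, {})

    md = [_MD_HEADER.format(title=name)]
    if markdown_cells >= 2:
        md.append(_MD_BODY)
    for extra in range(markdown_cells - 2):
        md.append(f"Paragraph {extra + 2} describes the next step in the "
                  "analysis and links the results together.\n")
    if bilingual:
        md.append(_MD_FRENCH)

    code: list[str] = []
    if behavior in (Behavior.CLEAN_IDENTICAL, Behavior.CLEAN_DIFFERENT,
                    Behavior.INSTALL_FAIL):
        code.extend(_prelude_cells(rng, uses_forgelib))
        if uses_local_module:
            code.append("import helpers\nprint('scaled', helpers.scale(total))\n")
        if style_violations:
            code.append("x=1\nresult = max(x,2)\ny = result;\n")
            code.append("counter = 0\nimport os\nprint(os.name, counter, y)\n")
        if behavior is Behavior.CLEAN_DIFFERENT:
            code.append("import secrets\nprint('token', secrets.token_hex(8))\n")
            if writes_file:
                code.append("with open('result.csv', 'w') as fh:\n"
                            "    fh.write('token,' + secrets.token_hex(4))\n")
    elif behavior is Behavior.TIMEOUT:
        code.append("import time\n")
        code.append(f"time.sleep({timeout_sleep})\nprint('woke up')\n")
    else:  # exception behaviors
        code.extend(_prelude_cells(rng, False))
        code.append(_FAILING_CELLS[behavior])
        code.append("print('never reached')\n")

    cells: list[dict[str, Any]] = []
    for i, text in enumerate(md):
        cells.append(notebook.markdown_cell(text))
        if i == 0:
            for _ in range(raw_cells):
                cells.append(notebook.raw_cell("raw directive block\n"))
    for src in code:
        cells.append(notebook.code_cell(src))
    return notebook.new_notebook(cells, json.loads(json.dumps(_PY_METADATA)))


def _execute_for_outputs(doc: dict[str, Any], nb_dir: Path,
                         pythonpath: Optional[str]) -> dict[str, Any]:
    """Run a forged notebook once at forge time to embed stored outputs."""
    import os
    from . import _runner
    nb_dir = nb_dir.resolve()
    nb_path = nb_dir / "_forge_tmp.ipynb"
    out_nb = nb_dir / "_forge_tmp.out.ipynb"
    out_trace = nb_dir / "_forge_tmp.trace.json"
    notebook.dump(doc, nb_path)
    env = dict(os.environ)
    env["PYTHONDONTWRITEBYTECODE"] = "1"  # keep forged trees byte-stable
    if pythonpath:
        env["PYTHONPATH"] = pythonpath
    proc = subprocess.run(
        [sys.executable, _runner.__file__, str(nb_path), str(out_nb),
         str(out_trace)],
        cwd=str(nb_dir), env=env, capture_output=True, text=True, timeout=120)
    trace = json.loads(out_trace.read_text())
    executed = notebook.load(out_nb)
    for path in (nb_path, out_nb, out_trace):
        path.unlink()
    if proc.returncode != 0 or not trace.get("completed"):
        raise RuntimeError(
            f"forged clean notebook failed to execute: {trace}")
    return executed


def _plant_stored_outputs(doc: dict[str, Any], rng: random.Random) -> None:
    """Seeded pseudo-outputs emulating a previous nondeterministic run."""
    count = 0
    for cell in doc["cells"]:
        if cell.get("cell_type") != "code":
            continue
        count += 1
        cell["execution_count"] = count
        src = notebook.source_text(cell)
        outputs = []
        if "secrets.token_hex(8)" in src:
            outputs.append({"output_type": "stream", "name": "stdout",
                            "text": f"token {rng.getrandbits(64):016x}\n"})
        elif "print('total', total)" in src:
            outputs.append({"output_type": "stream", "name": "stdout",
                            "text": "total 0\n"})  # placeholder, fixed below
        cell["outputs"] = outputs


# --------------------------------------------------------------------------
# repositories
# --------------------------------------------------------------------------

_SETUP_PY = """\
from setuptools import setup

setup(
    name="{name}",
    version="0.1.0",
    py_modules=["{module}"],
    install_requires=["forgelib"],
)
"""

_HELPERS_PY = """\
def scale(x, factor=2):
    return x * factor
"""


@dataclass
class _RepoPlan:
    slug: str
    declarations: tuple[str, ...]     # subset of {requirements, setup, pipfile}
    requirement: str = FORGE_PACKAGE
    notebooks: list[tuple[str, Behavior, dict]] = field(default_factory=list)
    available: bool = True


def _default_plan(timeout_sleep: float) -> list[_RepoPlan]:
    nb = lambda name, behavior, **kw: (name, behavior, kw)  # noqa: E731
    return [
        _RepoPlan("alpha-clean-reqs", ("requirements",), notebooks=[
            nb("overview_analysis.ipynb", Behavior.CLEAN_IDENTICAL,
               uses_forgelib=True, markdown_cells=2),
            nb("notebooks/summary_stats.ipynb", Behavior.CLEAN_IDENTICAL,
               markdown_cells=3, raw_cells=1),
            nb("notebooks/sampling_draws.ipynb", Behavior.CLEAN_DIFFERENT,
               writes_file=True),
        ]),
        _RepoPlan("beta-clean-setup", ("setup",), notebooks=[
            nb("demo.ipynb", Behavior.CLEAN_IDENTICAL, uses_forgelib=True),
            nb("random_walk.ipynb", Behavior.CLEAN_DIFFERENT),
        ]),
        _RepoPlan("gamma-clean-pipfile", ("pipfile",), notebooks=[
            nb("pipeline_check.ipynb", Behavior.CLEAN_IDENTICAL,
               uses_forgelib=True),
            nb("monte_carlo.ipynb", Behavior.CLEAN_DIFFERENT),
        ]),
        _RepoPlan("delta-nodeps", (), notebooks=[
            nb("Untitled3.ipynb", Behavior.CLEAN_IDENTICAL, markdown_cells=1),
            nb("figures/figure_2 (copy).ipynb", Behavior.CLEAN_IDENTICAL,
               markdown_cells=2, bilingual=True),
            nb("local_import_test.ipynb", Behavior.CLEAN_IDENTICAL,
               uses_local_module=True),
            nb("shuffle_experiment.ipynb", Behavior.CLEAN_DIFFERENT),
        ]),
        _RepoPlan("epsilon-errors-one", (), notebooks=[
            nb(f"{label.value[4:].lower()}_{i}.ipynb", label)
            for label in (Behavior.EXC_MODULENOTFOUND,
                          Behavior.EXC_FILENOTFOUND, Behavior.EXC_IMPORT,
                          Behavior.EXC_NAME, Behavior.EXC_IO)
            for i in (1, 2)
        ]),
        _RepoPlan("zeta-errors-two", (), notebooks=[
            nb(f"{label.value[4:].lower()}_{i}.ipynb", label)
            for label in (Behavior.EXC_ATTRIBUTE, Behavior.EXC_VALUE,
                          Behavior.EXC_TYPE, Behavior.EXC_KEY)
            for i in (1, 2)
        ] + [nb("styled_messy.ipynb", Behavior.CLEAN_IDENTICAL,
                style_violations=True)]),
        _RepoPlan("eta-timeout", (), notebooks=[
            nb("long_running_1.ipynb", Behavior.TIMEOUT),
            nb("long_running_2.ipynb", Behavior.TIMEOUT),
        ]),
        _RepoPlan("theta-foreign", (), notebooks=[
            nb("r_analysis_1.ipynb", Behavior.NON_TARGET_KERNEL),
            nb("r_analysis_2.ipynb", Behavior.NON_TARGET_KERNEL),
            nb("legacy_nolang_1.ipynb", Behavior.UNKNOWN_LANGUAGE),
            nb("legacy_nolang_2.ipynb", Behavior.UNKNOWN_LANGUAGE),
        ]),
        _RepoPlan("iota-badreqs", ("requirements",),
                  requirement=MISSING_PACKAGE, notebooks=[
            nb("wanted_analysis.ipynb", Behavior.INSTALL_FAIL),
            nb("second_attempt.ipynb", Behavior.INSTALL_FAIL),
        ]),
        _RepoPlan("kappa-missing", (), available=False),
    ]


def forge_repository(plan: _RepoPlan, workspace: Path, rng: random.Random,
                     timeout_sleep: float, forge_pythonpath: Optional[str]
                     ) -> tuple[RepoSpec, list[NotebookSpec]]:
    """Materialize one repository tree plus its manifest entries."""
    owner = f"lab-{plan.slug.split('-')[0]}"
    name = plan.slug
    rel_path = f"repos/{plan.slug}" if plan.available else None
    spec = RepoSpec(slug=plan.slug, owner=owner, name=name,
                    available=plan.available,
                    has_requirements="requirements" in plan.declarations,
                    has_setup="setup" in plan.declarations,
                    has_pipfile="pipfile" in plan.declarations,
                    path=rel_path)
    nb_specs: list[NotebookSpec] = []
    if not plan.available:
        return spec, nb_specs

    root = workspace / rel_path
    root.mkdir(parents=True, exist_ok=True)
    if spec.has_requirements:
        (root / "requirements.txt").write_text(plan.requirement + "\n")
    if spec.has_setup:
        module = plan.slug.replace("-", "_")
        (root / "setup.py").write_text(
            _SETUP_PY.format(name=plan.slug, module=module))
        (root / f"{module}.py").write_text(_HELPERS_PY)
    if spec.has_pipfile:
        (root / "Pipfile").write_text(
            '[[source]]\nname = "local"\nurl = "file:///dev/null"\n'
            'verify_ssl = false\n\n[packages]\nforgelib = "*"\n')
    (root / "README.md").write_text(f"# {plan.slug}\n\nForged fixture repo.\n")

    for nb_rel, behavior, kwargs in plan.notebooks:
        nb_path = root / nb_rel
        nb_path.parent.mkdir(parents=True, exist_ok=True)
        doc = forge_notebook(behavior, name=Path(nb_rel).stem, rng=rng,
                             timeout_sleep=timeout_sleep, **kwargs)
        if kwargs.get("uses_local_module"):
            (nb_path.parent / "helpers.py").write_text(_HELPERS_PY)
        if behavior is Behavior.CLEAN_IDENTICAL:
            doc = _execute_for_outputs(doc, nb_path.parent, forge_pythonpath)
        elif behavior is Behavior.CLEAN_DIFFERENT:
            _plant_stored_outputs(doc, rng)
            # the deterministic prelude's stored output must be truthful
            doc = _fix_deterministic_streams(doc)
            if kwargs.get("writes_file"):
                (nb_path.parent / "result.csv").write_text(
                    f"token,{rng.getrandbits(16):04x}")
        notebook.dump(doc, nb_path)
        if behavior is Behavior.CLEAN_IDENTICAL and rng.random() < 0.5:
            # stored checkpoint copies must be ignored downstream
            ckpt = nb_path.parent / ".ipynb_checkpoints"
            ckpt.mkdir(exist_ok=True)
            notebook.dump(doc, ckpt / nb_path.name)
        raised, canonical = EXCEPTION_NAMES.get(behavior, (None, None))
        counts = {t: sum(1 for c in doc["cells"] if c["cell_type"] == t)
                  for t in ("code", "markdown", "raw")}
        nb_specs.append(NotebookSpec(
            repo=plan.slug, path=nb_rel, behavior=behavior,
            expected_outcome=EXPECTED_OUTCOME[behavior],
            expected_exception=canonical, raised_exception=raised,
            code_cells=counts["code"], markdown_cells=counts["markdown"],
            raw_cells=counts["raw"]))
    return spec, nb_specs


def _fix_deterministic_streams(doc: dict[str, Any]) -> dict[str, Any]:
    """Recompute the deterministic prelude's stored stdout truthfully."""
    total = None
    for cell in doc["cells"]:
        if cell.get("cell_type") != "code":
            continue
        src = notebook.source_text(cell)
        if "values = [n * n for n in range(" in src:
            k = int(src.split("range(")[1].split(")")[0])
            total = sum(n * n for n in range(k))
        if "print('total', total)" in src and total is not None:
            cell["outputs"] = [{"output_type": "stream", "name": "stdout",
                                "text": f"total {total}\n"}]
    return doc


# --------------------------------------------------------------------------
# articles
# --------------------------------------------------------------------------

MESH_TABLE = {
    "Genomics": "Natural Science Disciplines",
    "Computational Biology": "Natural Science Disciplines",
    "Neoplasms": "Diseases",
    "Breast Neoplasms": "Diseases",
    "Software": "Information Science",
    "Machine Learning": "Information Science",
    "Diseases": "Diseases",
    "Information Science": "Information Science",
}

_JOURNALS = [
    ("2041-1723", "Nature Communications"),
    ("2050-084X", "eLife"),
    ("1553-7358", "PLoS Computational Biology"),
]

_DIALECT_TEMPLATES = {
    "plain": "https://github.com/{owner}/{name}",
    "blob_path": "https://github.com/{owner}/{name}/blob/main/overview_analysis.ipynb",
    "tree_path": "https://github.com/{owner}/{name}/tree/main/notebooks",
    "nbviewer": "https://nbviewer.jupyter.org/github/{owner}/{name}/blob/main/demo.ipynb",
    "raw_host": "https://raw.githubusercontent.com/{owner}/{name}/main/requirements.txt",
    "git_suffix": "https://github.com/{owner}/{name}.git",
    "schemeless": "github.com/{owner}/{name}",
    "trailing_slash": "https://github.com/{owner}/{name}/",
}


def _jats_skeleton(spec: ArticleSpec, rng: random.Random) -> etree._Element:
    nsmap = {"xlink": "http://www.w3.org/1999/xlink"}
    article = etree.Element("article", nsmap=nsmap)
    front = etree.SubElement(article, "front")
    jmeta = etree.SubElement(front, "journal-meta")
    jid = etree.SubElement(jmeta, "journal-id",
                           attrib={"journal-id-type": "nlm-ta"})
    jid.text = spec.journal_title.replace(" ", "-")[:12]
    tgroup = etree.SubElement(jmeta, "journal-title-group")
    etree.SubElement(tgroup, "journal-title").text = spec.journal_title
    etree.SubElement(jmeta, "issn").text = spec.journal_issn
    publisher = etree.SubElement(jmeta, "publisher")
    etree.SubElement(publisher, "publisher-name").text = "Forge Press"

    ameta = etree.SubElement(front, "article-meta")
    for id_type, value in (("pmc", spec.pmc_id),
                           ("pmid", str(rng.randint(30000000, 39999999))),
                           ("doi", f"10.9999/forge.{spec.pmc_id.lower()}")):
        aid = etree.SubElement(ameta, "article-id",
                               attrib={"pub-id-type": id_type})
        aid.text = value
    cats = etree.SubElement(ameta, "article-categories")
    mesh_group = etree.SubElement(cats, "subj-group",
                                  attrib={"subj-group-type": "mesh-heading"})
    for term in spec.mesh_terms:
        etree.SubElement(mesh_group, "subject").text = term
    tg = etree.SubElement(ameta, "title-group")
    etree.SubElement(tg, "article-title").text = spec.title
    contrib_group = etree.SubElement(ameta, "contrib-group")
    for _ in range(rng.randint(1, 3)):
        contrib = etree.SubElement(contrib_group, "contrib",
                                   attrib={"contrib-type": "author"})
        nm = etree.SubElement(contrib, "name")
        etree.SubElement(nm, "surname").text = rng.choice(
            ["Ngai", "Okafor", "Svensson", "Marchetti", "Oyelaran"])
        etree.SubElement(nm, "given-names").text = rng.choice(
            ["A.", "B.", "R.", "M.", "K."])
    year = rng.randint(2019, 2023)
    pub = etree.SubElement(ameta, "pub-date", attrib={"pub-type": "epub"})
    etree.SubElement(pub, "day").text = str(rng.randint(1, 28))
    etree.SubElement(pub, "month").text = str(rng.randint(1, 12))
    etree.SubElement(pub, "year").text = str(year)
    history = etree.SubElement(ameta, "history")
    rec = etree.SubElement(history, "date", attrib={"date-type": "received"})
    etree.SubElement(rec, "day").text = "1"
    etree.SubElement(rec, "month").text = "1"
    etree.SubElement(rec, "year").text = str(year - 1)
    perms = etree.SubElement(ameta, "permissions")
    etree.SubElement(perms, "copyright-statement").text = \
        f"(c) {year} the authors"
    lic = etree.SubElement(perms, "license")
    etree.SubElement(lic, "license-p").text = "CC BY 4.0"
    kwd_group = etree.SubElement(ameta, "kwd-group")
    for kw in spec.keywords:
        etree.SubElement(kwd_group, "kwd").text = kw
    return article


def forge_article(spec: ArticleSpec, rng: random.Random) -> bytes:
    """Valid JATS document with links planted per the article spec."""
    article = _jats_skeleton(spec, rng)
    front = article.find("front")
    ameta = front.find("article-meta")
    abstract = etree.SubElement(ameta, "abstract")
    abstract_p = etree.SubElement(abstract, "p")
    abstract_p.text = "We analyze forged data with open notebooks. "

    body = etree.SubElement(article, "body")
    sec = etree.SubElement(body, "sec")
    etree.SubElement(sec, "title").text = "Methods"
    body_p = etree.SubElement(sec, "p")
    body_p.text = "Code is archived publicly. "
    data_sec = etree.SubElement(body, "sec",
                                attrib={"sec-type": "data-availability"})
    data_p = etree.SubElement(data_sec, "p")
    data_p.text = "Data and code: "
    supp_sec = etree.SubElement(body, "sec",
                                attrib={"sec-type": "supplementary-material"})
    supp_p = etree.SubElement(supp_sec, "p")
    supp_p.text = "Additional material: "

    targets = {"abstract": abstract_p, "body": body_p,
               "data-availability": data_p,
               "supplementary-material": supp_p}
    xlink = "{http://www.w3.org/1999/xlink}href"
    for planted in spec.planted_links:
        parent = targets[planted.section]
        if planted.dialect in ("nbviewer", "blob_path"):
            # encode as an ext-link element with an href attribute
            link = etree.SubElement(parent, "ext-link",
                                    attrib={"ext-link-type": "uri",
                                            xlink: planted.raw})
            link.text = "notebook archive"
            link.tail = " "
        else:
            parent.text = (parent.text or "") + planted.raw + " ; "
    for rejection in spec.planted_rejections:
        data_p.text = (data_p.text or "") + rejection["raw"] + " "
    return etree.tostring(article, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _default_articles(repos: list[RepoSpec],
                      rng: random.Random) -> list[ArticleSpec]:
    by_slug = {r.slug: r for r in repos}

    def link(slug: str, dialect: str, section: str) -> PlantedLink:
        repo = by_slug[slug]
        raw = _DIALECT_TEMPLATES[dialect].format(owner=repo.owner,
                                                 name=repo.name)
        return PlantedLink(repo=slug, dialect=dialect, section=section,
                           raw=raw)

    mesh_choices = list(MESH_TABLE)
    specs = []
    assignments = [
        # (pmc suffix, journal index, [(slug, dialect, section)...], rejections)
        ("PMC9000001", 0, [("alpha-clean-reqs", "plain", "abstract"),
                           ("alpha-clean-reqs", "blob_path", "data-availability"),
                           ("beta-clean-setup", "git_suffix", "body")],
         [{"raw": "https://github.com/lab-alpha", "reason": "owner_only"}]),
        ("PMC9000002", 1, [("gamma-clean-pipfile", "nbviewer", "body"),
                           ("delta-nodeps", "tree_path", "data-availability")],
         [{"raw": "https://lab-gamma.github.io/site", "reason": "pages_site"}]),
        ("PMC9000003", 1, [("epsilon-errors-one", "raw_host", "body"),
                           ("zeta-errors-two", "schemeless", "data-availability")],
         []),
        ("PMC9000004", 2, [("eta-timeout", "plain", "supplementary-material"),
                           ("theta-foreign", "trailing_slash", "body")],
         []),
        ("PMC9000005", 0, [("iota-badreqs", "plain", "data-availability"),
                           ("kappa-missing", "plain", "body")],
         [{"raw": "https://gist.github.com/lab-iota/abc123",
           "reason": "non_repo_host"}]),
    ]
    for pmc_id, j_idx, planted, rejections in assignments:
        issn, title = _JOURNALS[j_idx]
        specs.append(ArticleSpec(
            pmc_id=pmc_id,
            title=f"Forged study {pmc_id[-1]}: reproducible notebooks",
            journal_issn=issn, journal_title=title,
            planted_links=[link(*p) for p in planted],
            planted_rejections=rejections,
            mesh_terms=rng.sample(mesh_choices, k=rng.randint(1, 3)),
            keywords=rng.sample(["notebooks", "reproducibility", "python",
                                 "workflows", "automation"],
                                k=rng.randint(1, 3)),
            xml_path=f"articles/{pmc_id}.xml"))
    return specs


# --------------------------------------------------------------------------
# corpus
# --------------------------------------------------------------------------

def forge_corpus(out_dir: str | Path, seed: int,
                 timeout_sleep: float = 25.0) -> ForgeManifest:
    """Generate the default labeled corpus under *out_dir*.

    Deterministic in (seed, timeout_sleep): the manifest and every
    forged file are byte-stable across runs.  The default corpus holds
    ~38 notebooks covering all 15 behavior labels at least twice.
    """
    workspace = Path(out_dir)
    workspace.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    forge_src = publish_package(workspace / "index").resolve()

    repos: list[RepoSpec] = []
    nb_specs: list[NotebookSpec] = []
    for plan in _default_plan(timeout_sleep):
        repo_spec, specs = forge_repository(plan, workspace, rng,
                                            timeout_sleep, str(forge_src))
        repos.append(repo_spec)
        nb_specs.extend(specs)

    articles = _default_articles(repos, rng)
    for spec in articles:
        path = workspace / spec.xml_path
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(forge_article(spec, rng))

    (workspace / "mesh_table.json").write_text(
        json.dumps(MESH_TABLE, indent=1, sort_keys=True))
    manifest = ForgeManifest(seed=seed, timeout_sleep=timeout_sleep,
                             articles=articles, repos=repos,
                             notebooks=nb_specs)
    (workspace / "manifest.json").write_text(manifest.to_json())
    return manifest
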