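"""Pedigree data model and I/O.

A pedigree is a set of individuals with two-parent links (a listed parent with
no recorded partner gets an auto-created unobserved founder, censored at age
0, which contributes no information).  Phenotypes are first breast/ovarian
cancer diagnosis ages, a tumour-marker panel on the breast tumour, and a
mutation-test result.  Ages are integer years; a diagnosis occurs at the
start of the stated year and there is no follow-up after it.

The CSV dialect has one row per individual with columns::

    id,sex,father_id,mother_id,birth_year,observation_age,
    breast_cancer_age,ovarian_cancer_age,er,pr,her2,ck5_6,ck14,genetic_test

Marker cells take ``positive``/``negative``/``untested`` (empty = untested);
``genetic_test`` takes ``untested``/``negative``/``brca1_positive``/
``brca2_positive``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .errors import PanelError, PedigreeError

MARKER_STATES = ("positive", "negative", "untested")
GENETIC_TEST_STATES = ("untested", "negative", "brca1_positive", "brca2_positive")

#: End-point keys produced by panel classification, finest observed first.
ENDPOINT_KEYS = (
    "total", "er_positive", "er_negative", "er_negative_non_tn", "tn",
    "tn_both_ck_positive", "tn_one_ck_positive", "tn_no_ck_positive",
    "tn_ck56_positive", "tn_ck56_negative",
    "tn_ck14_positive", "tn_ck14_negative",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Per-marker assay state for one breast tumour."""

    er: str = "untested"
    pr: str = "untested"
    her2: str = "untested"
    ck5_6: str = "untested"
    ck14: str = "untested"

    def __post_init__(self):
        for name in ("er", "pr", "her2", "ck5_6", "ck14"):
            if getattr(self, name) not in MARKER_STATES:
                raise PanelError(f"invalid state {getattr(self, name)!r} for {name}")

    @property
    def all_untested(self) -> bool:
        return all(getattr(self, m) == "untested"
                   for m in ("er", "pr", "her2", "ck5_6", "ck14"))

    def classify(self) -> str:
        """Map the panel to the finest observed end point.

        Markers below an unresolved layer are marginalized (e.g. PR/HER2
        without ER status leave the tumour at ``total``); cytokeratin results
        are only meaningful on an established triple-negative tumour and are
        rejected otherwise.
        """
        ck_tested = self.ck5_6 != "untested" or self.ck14 != "untested"
        tn = self.er == "negative" and self.pr == "negative" and self.her2 == "negative"
        if ck_tested and not tn:
            raise PanelError(
                "cytokeratin status recorded on a tumour not established "
                "triple-negative (requires ER-, PR-, HER2- all tested negative)")
        if self.er == "untested":
            return "total"
        if self.er == "positive":
            return "er_positive"
        if self.pr == "positive" or self.her2 == "positive":
            return "er_negative_non_tn"
        if not tn:  # PR or HER2 untested: TN layer unresolved
            return "er_negative"
        if self.ck5_6 != "untested" and self.ck14 != "untested":
            n_pos = (self.ck5_6 == "positive") + (self.ck14 == "positive")
            return ("tn_no_ck_positive", "tn_one_ck_positive",
                    "tn_both_ck_positive")[n_pos]
        if self.ck5_6 != "untested":
            return ("tn_ck56_positive" if self.ck5_6 == "positive"
                    else "tn_ck56_negative")
        if self.ck14 != "untested":
            return ("tn_ck14_positive" if self.ck14 == "positive"
                    else "tn_ck14_negative")
        return "tn"


UNTESTED_PANEL = MarkerPanel()


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "F" or "M"
    father_id: str | None = None
    mother_id: str | None = None
    birth_year: int | None = None
    observation_age: int | None = None
    breast_cancer_age: int | None = None
    ovarian_cancer_age: int | None = None
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    genetic_test: str = "untested"

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise PedigreeError(f"{self.id}: sex must be 'F' or 'M'")
        if self.genetic_test not in GENETIC_TEST_STATES:
            raise PedigreeError(f"{self.id}: invalid genetic_test "
                                f"{self.genetic_test!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def censor_age(self) -> int:
        """Age up to which this individual contributes information: the first
        cancer if any, else the observation age (0 when unknown)."""
        events = [a for a in (self.breast_cancer_age, self.ovarian_cancer_age)
                  if a is not None]
        if events:
            return min(events)
        return self.observation_age if self.observation_age is not None else 0


@dataclass(frozen=True)
class Issue:
    """One validation finding."""

    individual_id: str
    message: str

    def __str__(self) -> str:
        return f"{self.individual_id}: {self.message}"


class Pedigree:
    """An ordered collection of individuals with validated parent links."""

    def __init__(self, individuals: Iterable[Individual], auto_complete: bool = True):
        members = list(individuals)
        if not members:
            raise PedigreeError("pedigree is empty")
        if auto_complete:
            members = _complete_single_parents(members)
        self._members: dict[str, Individual] = {}
        for ind in members:
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeError(f"{ind.id}: single-parent individual "
                                    "(both parents or neither)")
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        for ind in members:
            for pid, want_sex, role in ((ind.father_id, "M", "father"),
                                        (ind.mother_id, "F", "mother")):
                if pid is None:
                    continue
                if pid not in self._members:
                    raise PedigreeError(f"{ind.id}: unknown {role} id {pid!r}")
                if self._members[pid].sex != want_sex:
                    raise PedigreeError(
                        f"{ind.id}: {role} {pid!r} has sex "
                        f"{self._members[pid].sex!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(i: str, stack: list[str]) -> None:
            if state.get(i) == 1:
                return
            if state.get(i) == 0:
                raise PedigreeError(
                    f"pedigree cycle through {' -> '.join(stack + [i])}")
            state[i] = 0
            ind = self._members[i]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [i])
            state[i] = 1

        for i in self._members:
            visit(i, [])

    # -- access -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self._members[ind_id]
        except KeyError:
            raise KeyError(f"no individual {ind_id!r} in pedigree") from None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._members)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def topological_order(self) -> list[Individual]:
        """Parents before children."""
        done: dict[str, None] = {}

        def visit(i: str) -> None:
            if i in done:
                return
            ind = self._members[i]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            done[i] = None

        for i in self._members:
            visit(i)
        return [self._members[i] for i in done]

    def ancestors(self, ind_id: str) -> set[str]:
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            ind = self._members[stack.pop()]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def with_member(self, ind: Individual) -> "Pedigree":
        """A copy with one individual replaced (same id)."""
        if ind.id not in self._members:
            raise KeyError(ind.id)
        return Pedigree(
            [ind if m.id == ind.id else m for m in self], auto_complete=False)


def _complete_single_parents(members: list[Individual]) -> list[Individual]:
    """Auto-create the missing partner of a listed parent as an unobserved
    founder censored at age 0; children sharing the same single listed parent
    share the auto-created partner."""
    ids = {m.id for m in members}
    created: dict[tuple[str, str], str] = {}
    out: list[Individual] = []
    new_founders: list[Individual] = []
    counter = 0
    for ind in members:
        fid, mid = ind.father_id, ind.mother_id
        if (fid is None) != (mid is None):
            present, missing_role = (mid, "father") if fid is None else (fid, "mother")
            key = (present, missing_role)
            if key not in created:
                counter += 1
                new_id = f"__founder{counter}"
                while new_id in ids:
                    counter += 1
                    new_id = f"__founder{counter}"
                ids.add(new_id)
                created[key] = new_id
                new_founders.append(Individual(
                    id=new_id, sex="M" if missing_role == "father" else "F"))
            if missing_role == "father":
                fid = created[key]
            else:
                mid = created[key]
            ind = replace(ind, father_id=fid, mother_id=mid)
        out.append(ind)
    return out + new_founders


# ---------------------------------------------------------------------------
# validation (reporting, non-raising)


def validate_pedigree(ped: Pedigree) -> list[Issue]:
    """All phenotype/marker/structure findings for a structurally parseable
    pedigree.  Blocking issues make the likelihood refuse the pedigree."""
    issues: list[Issue] = []
    for ind in ped:
        for name, age in (("breast_cancer_age", ind.breast_cancer_age),
                          ("ovarian_cancer_age", ind.ovarian_cancer_age)):
            if age is not None:
                if not 0 <= age < 80:
                    issues.append(Issue(ind.id, f"{name} {age} outside 0..79"))
                if ind.observation_age is not None and age > ind.observation_age:
                    issues.append(Issue(
                        ind.id, f"{name} {age} exceeds observation age "
                                f"{ind.observation_age}"))
        if ind.breast_cancer_age is None and not ind.panel.all_untested:
            issues.append(Issue(
                ind.id, "tumour markers recorded without a breast cancer diagnosis"))
        if ind.sex == "M" and ind.breast_cancer_age is not None:
            issues.append(Issue(
                ind.id, "male breast cancer is outside the model"))
        if ind.sex == "M" and ind.ovarian_cancer_age is not None:
            issues.append(Issue(ind.id, "ovarian cancer recorded for a male"))
        if ind.breast_cancer_age is not None:
            try:
                ind.panel.classify()
            except PanelError as exc:
                issues.append(Issue(ind.id, str(exc)))
        if not ind.is_founder:
            shared = ped.ancestors(ind.father_id) & ped.ancestors(ind.mother_id)
            shared |= ({ind.father_id} & ped.ancestors(ind.mother_id))
            shared |= ({ind.mother_id} & ped.ancestors(ind.father_id))
            if shared:
                issues.append(Issue(
                    ind.id, f"inbreeding loop: parents share ancestor(s) "
                            f"{sorted(shared)} (unsupported)"))
    return issues


# ---------------------------------------------------------------------------
# CSV I/O

CSV_COLUMNS = ("id", "sex", "father_id", "mother_id", "birth_year",
               "observation_age", "breast_cancer_age", "ovarian_cancer_age",
               "er", "pr", "her2", "ck5_6", "ck14", "genetic_test")


def _parse_int(cell: str, where: str) -> int | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return int(cell)
    except ValueError:
        raise PedigreeError(f"{where}: not an integer: {cell!r}")


def _parse_marker(cell: str, where: str) -> str:
    cell = cell.strip().lower()
    if not cell:
        return "untested"
    if cell not in MARKER_STATES:
        raise PedigreeError(f"{where}: invalid marker state {cell!r}")
    return cell


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse and validate a pedigree CSV file."""
    with open(path, newline="") as fh:
        return _read_pedigree_stream(fh, str(path))


def read_pedigree_string(text: str) -> Pedigree:
    return _read_pedigree_stream(io.StringIO(text), "<string>")


def _read_pedigree_stream(fh, name: str) -> Pedigree:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise PedigreeError(f"{name}: empty pedigree file")
    missing = set(CSV_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise PedigreeError(f"{name}: missing column(s) {sorted(missing)}")
    members = []
    for lineno, row in enumerate(reader, start=2):
        where = f"{name}:{lineno}"
        ind_id = (row.get("id") or "").strip()
        if not ind_id:
            raise PedigreeError(f"{where}: missing id")
        gt = (row.get("genetic_test") or "").strip().lower() or "untested"
        members.append(Individual(
            id=ind_id,
            sex=(row.get("sex") or "").strip().upper(),
            father_id=(row.get("father_id") or "").strip() or None,
            mother_id=(row.get("mother_id") or "").strip() or None,
            birth_year=_parse_int(row.get("birth_year") or "", where),
            observation_age=_parse_int(row.get("observation_age") or "", where),
            breast_cancer_age=_parse_int(row.get("breast_cancer_age") or "", where),
            ovarian_cancer_age=_parse_int(row.get("ovarian_cancer_age") or "", where),
            panel=MarkerPanel(
                er=_parse_marker(row.get("er") or "", where),
                pr=_parse_marker(row.get("pr") or "", where),
                her2=_parse_marker(row.get("her2") or "", where),
                ck5_6=_parse_marker(row.get("ck5_6") or "", where),
                ck14=_parse_marker(row.get("ck14") or "", where),
            ),
            genetic_test=gt,
        ))
    if not members:
        raise PedigreeError(f"{name}: pedigree file has no individuals")
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        _write_pedigree_stream(ped, fh)


def pedigree_to_string(ped: Pedigree) -> str:
    buf = io.StringIO()
    _write_pedigree_stream(ped, buf)
    return buf.getvalue()


def _write_pedigree_stream(ped: Pedigree, fh) -> None:
    writer = csv.writer(fh)
    writer.writerow(CSV_COLUMNS)
    for ind in ped:
        writer.writerow([
            ind.id, ind.sex, ind.father_id or "", ind.mother_id or "",
            "" if ind.birth_year is None else ind.birth_year,
            "" if ind.observation_age is None else ind.observation_age,
            "" if ind.breast_cancer_age is None else ind.breast_cancer_age,
            "" if ind.ovarian_cancer_age is None else ind.ovarian_cancer_age,
            _blank(ind.panel.er), _blank(ind.panel.pr), _blank(ind.panel.her2),
            _blank(ind.panel.ck5_6), _blank(ind.panel.ck14),
            "" if ind.genetic_test == "untested" else ind.genetic_test,
        ])


def _blank(state: str) -> str:
    return "" if state == "untested" else state


# ---------------------------------------------------------------------------
# example families


def single_case(
    diagnosis_age: int = 30,
    panel: MarkerPanel = UNTESTED_PANEL,
    birth_year: int = 1960,
    genetic_test: str = "untested",
) -> Pedigree:
    """A single affected woman with no informative relatives."""
    return Pedigree([Individual(
        id="proband", sex="F", birth_year=birth_year,
        observation_age=diagnosis_age, breast_cancer_age=diagnosis_age,
        panel=panel, genetic_test=genetic_test)])


def mother_daughter(
    proband_age: int = 40,
    mother_age: int = 50,
    mother_panel: MarkerPanel = UNTESTED_PANEL,
    proband_panel: MarkerPanel = UNTESTED_PANEL,
    proband_birth_year: int = 1960,
    mother_birth_year: int = 1935,
    proband_genetic_test: str = "untested",
) -> Pedigree:
    """An affected proband with an affected mother (father auto-created)."""
    return Pedigree([
        Individual(id="mother", sex="F", birth_year=mother_birth_year,
                   observation_age=mother_age, breast_cancer_age=mother_age,
                   panel=mother_panel),
        Individual(id="proband", sex="F", father_id=None, mother_id="mother",
                   birth_year=proband_birth_year, observation_age=proband_age,
                   breast_cancer_age=proband_age, panel=proband_panel,
                   genetic_test=proband_genetic_test),
    ])


def tested_negative_family(
    proband_age: int = 40,
    mother_age: int = 50,
    mother_panel: MarkerPanel = UNTESTED_PANEL,
    proband_panel: MarkerPanel = UNTESTED_PANEL,
    **kwargs,
) -> Pedigree:
    """The mother-daughter family with the proband mutation-tested negative."""
    return mother_daughter(proband_age, mother_age, mother_panel, proband_panel,
                           proband_genetic_test="negative", **kwargs)


def example_pedigrees() -> dict:
    """Named programmatic pedigree builders for the worked scenarios."""
    return {
        "single_case": single_case,
        "mother_daughter": mother_daughter,
        "tested_negative": tested_negative_family,
    }
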