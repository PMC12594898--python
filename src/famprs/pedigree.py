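"""Family structures, kinship, relationship degree, and case-relative pairs.

Pedigrees arrive in the PLINK ``.fam`` / ``.ped`` first-six-column dialect
(family, individual, father, mother, sex, phenotype; '0' = unknown parent;
sex 1=male 2=female).  A phenotype roster can overlay affection status,
ages and history flags.

Kinship is the classical recursive coefficient (parent-child 1/4,
grandparent 1/8, founders pairwise unrelated).  Relationship degree is
classified by path type, not by the raw kinship value, so inbreeding can
never promote a pair's degree: first degree = parent/offspring/full
sibling; second = grandparent/grandchild, half-sibling, aunt-niece; any
other nonzero-kinship pair is third-plus.

Pair enumeration builds the within-family comparison groups: for every
affected female, one pair per eligible unaffected female relative of the
requested class, so a case appears as many times as she has relatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .scoring import PRSTable

logger = logging.getLogger(__name__)

PAIR_GROUPS = ("sisters", "mothers", "daughters", "first_second", "total_relatives")

_SEX_CODES = {"1": "male", "2": "female"}
_PHENO_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # female | male | unknown
    affection: str = "unknown"  # affected | unaffected | unknown
    age: float | None = None
    age_at_onset: float | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A family graph keyed by individual id (ids unique across families)."""

    def __init__(self) -> None:
        self.members: dict[str, Individual] = {}
        self._kin_cache: dict[tuple[str, str], float] = {}
        self._depth: dict[str, int] | None = None

    def add(self, ind: Individual) -> None:
        if ind.individual_id in self.members:
            raise ValueError(
                f"duplicate individual id {ind.individual_id!r} "
                f"(family {ind.family_id})"
            )
        self.members[ind.individual_id] = ind
        self._kin_cache.clear()
        self._depth = None

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self.members[iid]
        except KeyError:
            raise KeyError(f"unknown individual {iid!r}") from None

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self[iid]
        return ind.father_id, ind.mother_id

    def known_parents(self, iid: str) -> list[str]:
        return [p for p in self.parents(iid) if p is not None]

    @property
    def founders(self) -> list[str]:
        return [i for i, m in self.members.items() if m.is_founder]

    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members.values():
            seen.setdefault(m.family_id, None)
        return list(seen)

    def family_members(self, family_id: str) -> list[str]:
        return [i for i, m in self.members.items() if m.family_id == family_id]

    # -- structural validation ------------------------------------------------

    def validate(self) -> None:
        """Check parent resolution, parental sex consistency and acyclicity."""
        for iid, ind in self.members.items():
            for pid, want in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise ValueError(f"{iid}: parent {pid!r} not in pedigree")
                psex = self.members[pid].sex
                if psex != "unknown" and psex != want:
                    role = "father" if want == "male" else "mother"
                    raise ValueError(f"{iid}: {role} {pid!r} is recorded as {psex}")
        self._compute_depths()  # raises on cycles

    def _compute_depths(self) -> dict[str, int]:
        """Generation index: founders 0, else 1 + max(parent depths).

        Iterative resolution; an unresolvable individual implies a cycle.
        """
        if self._depth is not None:
            return self._depth
        depth: dict[str, int] = {}
        pending = set(self.members)
        while pending:
            progressed = False
            for iid in list(pending):
                ps = [p for p in self.known_parents(iid) if p in self.members]
                if iid in ps:
                    raise ValueError(f"cycle detected: {iid} is its own parent")
                if all(p in depth for p in ps):
                    depth[iid] = 1 + max((depth[p] for p in ps), default=-1)
                    pending.discard(iid)
                    progressed = True
            if not progressed:
                raise ValueError(
                    f"cycle detected in pedigree involving: {sorted(pending)[:5]}"
                )
        self._depth = depth
        return depth

    # -- kinship --------------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Recursive kinship coefficient; founders are outbred and pairwise
        unrelated, so phi(founder, founder) = 1/2 on the diagonal and 0 off
        it."""
        if a not in self.members:
            raise KeyError(f"unknown individual {a!r}")
        if b not in self.members:
            raise KeyError(f"unknown individual {b!r}")
        depth = self._compute_depths()
        return self._kin(a, b, depth)

    def _kin(self, a: str, b: str, depth: dict[str, int]) -> float:
        key = (a, b) if a <= b else (b, a)
        hit = self._kin_cache.get(key)
        if hit is not None:
            return hit
        if a == b:
            fa, mo = self.parents(a)
            inb = self._kin(fa, mo, depth) if fa is not None and mo is not None else 0.0
            val = 0.5 + 0.5 * inb
        else:
            # recurse on the later-generation member, which cannot be an
            # ancestor of the other
            if depth[a] < depth[b]:
                a, b = b, a
            fa, mo = self.parents(a)
            if fa is None and mo is None:
                val = 0.0
            else:
                val = 0.5 * sum(self._kin(p, b, depth) for p in (fa, mo) if p is not None)
        self._kin_cache[key] = val
        return val

    # -- relationship classification -------------------------------------------

    def _full_siblings(self, a: str, b: str) -> bool:
        pa, pb = self.known_parents(a), self.known_parents(b)
        return len(pa) == 2 and set(pa) == set(pb)

    def _half_siblings(self, a: str, b: str) -> bool:
        pa, pb = set(self.known_parents(a)), set(self.known_parents(b))
        return len(pa & pb) == 1 and not self._full_siblings(a, b)

    def _grandparents(self, iid: str) -> set[str]:
        out: set[str] = set()
        for p in self.known_parents(iid):
            out.update(self.known_parents(p))
        return out

    def relationship(self, case: str, relative: str) -> tuple[str, str]:
        """Classify (degree, label) of ``relative`` with respect to ``case``.

        degree in {'1', '2', '3+', 'unrelated'}; label in {mother, daughter,
        full-sister, half-sister, grandmother, granddaughter, aunt, niece,
        other, none}.  Labels assume the female pairing context; the degree
        logic is sex-free.
        """
        if self[case].family_id != self[relative].family_id:
            return "unrelated", "none"
        if relative in self.known_parents(case):
            return "1", "mother" if self[relative].sex != "male" else "other"
        if case in self.known_parents(relative):
            return "1", "daughter" if self[relative].sex != "male" else "other"
        if self._full_siblings(case, relative):
            return "1", "full-sister" if self[relative].sex != "male" else "other"
        if self._half_siblings(case, relative):
            return "2", "half-sister" if self[relative].sex != "male" else "other"
        if relative in self._grandparents(case):
            return "2", "grandmother" if self[relative].sex != "male" else "other"
        if case in self._grandparents(relative):
            return "2", "granddaughter" if self[relative].sex != "male" else "other"
        # aunt/uncle: full sibling of a parent; niece/nephew: the converse
        for p in self.known_parents(case):
            if self._full_siblings(p, relative):
                return "2", "aunt" if self[relative].sex != "male" else "other"
        for p in self.known_parents(relative):
            if self._full_siblings(p, case):
                return "2", "niece" if self[relative].sex != "male" else "other"
        if self.kinship(case, relative) > 0:
            return "3+", "other"
        return "unrelated", "none"

    def classify_degree(self, a: str, b: str) -> str:
        """Relationship degree of a pair: '1', '2', '3+' or 'unrelated'."""
        return self.relationship(a, b)[0]


def parse_pedigree(source, roster: pd.DataFrame | None = None) -> Pedigree:
    """Parse a PLINK .fam/.ped 6-column table and optionally overlay a roster.

    The roster (indexed or keyed by ``sample_id``) may carry ``sex``,
    ``affection``, ``age`` and ``age_at_onset`` columns that override the
    .fam codes.
    """
    df = pd.read_csv(
        source,
        sep=r"\s+",
        header=None,
        usecols=range(6),
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    ped = Pedigree()
    for rec in df.itertuples(index=False):
        ped.add(
            Individual(
                family_id=rec.family_id,
                individual_id=rec.individual_id,
                father_id=None if rec.father_id == "0" else rec.father_id,
                mother_id=None if rec.mother_id == "0" else rec.mother_id,
                sex=_SEX_CODES.get(rec.sex, "unknown"),
                affection=_PHENO_CODES.get(rec.phenotype, "unknown"),
            )
        )
    if roster is not None:
        apply_roster(ped, roster)
    ped.validate()
    return ped


def apply_roster(ped: Pedigree, roster: pd.DataFrame) -> None:
    """Overlay affection/sex/ages from a phenotype roster onto a pedigree."""
    df = roster
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    for iid, row in df.iterrows():
        if iid not in ped:
            continue
        ind = ped[iid]
        if "sex" in row and pd.notna(row["sex"]):
            ind.sex = str(row["sex"])
        if "affection" in row and pd.notna(row["affection"]):
            ind.affection = str(row["affection"])
        elif "bc_status" in row and pd.notna(row["bc_status"]):
            ind.affection = "affected" if row["bc_status"] == "case" else "unaffected"
        if "age" in row and pd.notna(row["age"]):
            ind.age = float(row["age"])
        if "age_at_onset" in row and pd.notna(row["age_at_onset"]):
            ind.age_at_onset = float(row["age_at_onset"])


@dataclass
class PairSet:
    """Case-relative pairs for one named relationship group.

    ``pairs`` columns: case_id, relative_id, relationship, degree.  A case
    appears once per eligible relative; relatives may recur across cases.
    ``n_dropped_missing_prs`` counts pairs discarded because a member lacked
    a score.
    """

    group_name: str
    pairs: pd.DataFrame
    n_dropped_missing_prs: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        out = self.pairs.copy()
        out.insert(0, "group", self.group_name)
        out.to_csv(path, sep="\t", index=False)


def _eligible(group: str, degree: str, label: str) -> bool:
    if group == "sisters":
        return label == "full-sister"
    if group == "mothers":
        return label == "mother"
    if group == "daughters":
        return label == "daughter"
    if group == "first_second":
        return degree in ("1", "2")
    if group == "total_relatives":
        return degree != "unrelated"
    raise ValueError(f"unknown pair group {group!r}")


def enumerate_pairs(
    ped: Pedigree,
    group_name: str,
    prs: PRSTable | None = None,
    deduplicate_relatives: bool = False,
) -> PairSet:
    """Build the case-relative pairs of one group.

    Cases are affected females; eligible relatives are unaffected females of
    the same family in the requested relationship class (blood relatives
    only — marriage links carry zero kinship and never pair).  Individuals
    of unknown affection sit on neither side.  With ``prs`` given, pairs
    whose members lack a z-score are dropped and counted.  With
    ``deduplicate_relatives`` a relative is used by at most one case (first
    case in id order), for sensitivity analysis of relative re-use.
    """
    _eligible(group_name, "1", "mother")  # validates the group name early
    rows = []
    by_family: dict[str, list[str]] = {}
    for iid, m in ped.members.items():
        by_family.setdefault(m.family_id, []).append(iid)
    used_relatives: set[str] = set()
    for fam, members in by_family.items():
        cases = sorted(
            i for i in members
            if ped[i].affection == "affected" and ped[i].sex == "female"
        )
        candidates = sorted(
            i for i in members
            if ped[i].affection == "unaffected" and ped[i].sex == "female"
        )
        for case in cases:
            for rel in candidates:
                if rel == case:
                    continue
                degree, label = ped.relationship(case, rel)
                if not _eligible(group_name, degree, label):
                    continue
                if deduplicate_relatives and rel in used_relatives:
                    continue
                used_relatives.add(rel)
                rows.append((case, rel, label, degree))
    pairs = pd.DataFrame(rows, columns=["case_id", "relative_id", "relationship", "degree"])
    n_dropped = 0
    if prs is not None and len(pairs):
        z = prs.z
        have = pairs["case_id"].isin(z.index) & pairs["relative_id"].isin(z.index)
        scored = have.copy()
        scored[have] = (
            z.loc[pairs.loc[have, "case_id"]].notna().to_numpy()
            & z.loc[pairs.loc[have, "relative_id"]].notna().to_numpy()
        )
        n_dropped = int((~scored).sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d pair(s) lacking a PRS z-score", group_name, n_dropped
            )
        pairs = pairs[scored].reset_index(drop=True)
        pairs["case_prs"] = z.loc[pairs["case_id"]].to_numpy()
        pairs["relative_prs"] = z.loc[pairs["relative_id"]].to_numpy()
    return PairSet(group_name, pairs, n_dropped_missing_prs=n_dropped)


def enumerate_all_groups(
    ped: Pedigree,
    prs: PRSTable | None = None,
    deduplicate_relatives: bool = False,
) -> dict[str, PairSet]:
    """All five comparison groups in canonical order."""
    return {
        g: enumerate_pairs(ped, g, prs=prs, deduplicate_relatives=deduplicate_relatives)
        for g in PAIR_GROUPS
    }


def write_fam(ped: Pedigree, path) -> None:
    """Write the pedigree back out in PLINK .fam dialect."""
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for iid, m in ped.members.items():
            fh.write(
                f"{m.family_id}\t{iid}\t{m.father_id or '0'}\t{m.mother_id or '0'}\t"
                f"{sex_code[m.sex]}\t{pheno_code[m.affection]}\n"
            )
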