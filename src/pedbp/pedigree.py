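"""Pedigree structures, a synthetic extended-family generator, and the
additive relationship matrix.

A pedigree is a directed acyclic graph of parent-offspring links.  The
additive (numerator) relationship matrix ``A`` gives, for every pair of
individuals, twice the kinship coefficient -- the expected fraction of
alleles shared identical by descent.  ``A`` is the covariance structure of
additive genetic values and is what variance-component heritability
estimation conditions on.

Monozygotic (MZ) twins are represented explicitly: the two members of an
``mz_group`` share a single genome, so their relationship entries (to each
other and to everyone else) are those of one genetic individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "PedigreeSet",
    "PedigreeError",
    "generate_pedigree_set",
    "additive_relationship",
    "read_pedigree",
    "write_pedigree",
]


class PedigreeError(ValueError):
    """Structural or configuration problem with a pedigree."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are either both set or both ``None``
    (founders).  ``mz_group`` labels monozygotic twin pairs; both members
    of a group have identical sex and identical parents.
    """

    person_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "male"  # "male" | "female"
    mz_group: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"{self.person_id}: father and mother must both be present or both absent"
            )
        if self.sex not in ("male", "female"):
            raise PedigreeError(f"{self.person_id}: invalid sex {self.sex!r}")


@dataclass
class PedigreeSet:
    """An ordered collection of individuals grouped into families."""

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {ind.person_id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise PedigreeError("duplicate person_id")
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals:
            if ind.father_id is not None:
                fa = self._by_id.get(ind.father_id)
                mo = self._by_id.get(ind.mother_id)
                if fa is None or mo is None:
                    raise PedigreeError(f"{ind.person_id}: parent not in pedigree")
                if fa.family_id != ind.family_id or mo.family_id != ind.family_id:
                    raise PedigreeError(f"{ind.person_id}: parent in different family")
                if fa.sex != "male" or mo.sex != "female":
                    raise PedigreeError(f"{ind.person_id}: parent sex inconsistent")
        for gid, members in self.mz_groups().items():
            if len(members) != 2:
                raise PedigreeError(f"MZ group {gid} must have exactly 2 members")
            a, b = members
            if a.sex != b.sex or (a.father_id, a.mother_id) != (b.father_id, b.mother_id):
                raise PedigreeError(f"MZ group {gid}: twins must share sex and parents")
        self.topological_order()  # raises on cycles

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, person_id: str) -> Individual:
        return self._by_id[person_id]

    def __contains__(self, person_id: str) -> bool:
        return person_id in self._by_id

    @property
    def person_ids(self) -> list[str]:
        return [ind.person_id for ind in self.individuals]

    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def family_sizes(self) -> dict[str, int]:
        return {fid: len(m) for fid, m in self.families().items()}

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def mz_groups(self) -> dict[str, list[Individual]]:
        groups: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            if ind.mz_group is not None:
                groups.setdefault(ind.mz_group, []).append(ind)
        return groups

    def topological_order(self) -> list[Individual]:
        """Individuals ordered parents-before-children (raises on cycles)."""
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(pid: str) -> None:
            st = state.get(pid)
            if st == 1:
                return
            if st == 0:
                raise PedigreeError("cycle in parentage")
            state[pid] = 0
            ind = self._by_id[pid]
            if ind.father_id is not None:
                visit(ind.father_id)
                visit(ind.mother_id)
            state[pid] = 1
            order.append(ind)

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * len(self.individuals) + 100))
        try:
            for ind in self.individuals:
                visit(ind.person_id)
        finally:
            sys.setrecursionlimit(old)
        return order

    def generation_depth(self) -> dict[str, int]:
        """0 for founders, 1 + max(parent depth) otherwise."""
        depth: dict[str, int] = {}
        for ind in self.topological_order():
            if ind.is_founder:
                depth[ind.person_id] = 0
            else:
                depth[ind.person_id] = 1 + max(depth[ind.father_id], depth[ind.mother_id])
        return depth


# ---------------------------------------------------------------------------
# Synthetic pedigree generation


def generate_pedigree_set(
    n_families: int = 20,
    size_range: tuple[int, int] = (21, 76),
    n_mz_pairs: int = 2,
    seed: int = 0,
) -> PedigreeSet:
    """Generate extended pedigrees emulating a large family study design.

    Each family starts from a founder couple; children either marry in a
    new founder spouse and reproduce or remain unmarried, until a target
    size (uniform within ``size_range``) is reached, always producing at
    least three generations.  ``n_mz_pairs`` families (at most one pair
    per family) contain a monozygotic twin pair.

    Deterministic for a fixed ``seed``.
    """
    lo, hi = size_range
    if hi < lo:
        raise PedigreeError(f"size_range max < min: {size_range}")
    if lo < 3:
        raise PedigreeError("size_range min must be >= 3")
    if n_mz_pairs > n_families:
        raise PedigreeError("cannot place more MZ pairs than families")
    rng = np.random.default_rng(np.random.SeedSequence([0x9ED1, int(seed)]))
    individuals: list[Individual] = []
    mz_counter = 0
    for f in range(n_families):
        # leave head-room of 4 so a forced third generation never overshoots hi
        target = int(rng.integers(lo, max(lo, hi - 4) + 1))
        want_mz = f < n_mz_pairs
        fam = _grow_family(f"F{f + 1:02d}", target, want_mz, mz_counter, rng)
        if want_mz:
            mz_counter += 1
        if not lo <= len(fam) <= hi:  # pragma: no cover - guarded by construction
            raise PedigreeError("family size fell outside requested range")
        individuals.extend(fam)
    return PedigreeSet(individuals)


def _grow_family(
    family_id: str, target: int, want_mz: bool, mz_counter: int, rng: np.random.Generator
) -> list[Individual]:
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{family_id}-{counter:03d}"

    members: list[Individual] = []

    def add(**kw) -> Individual:
        ind = Individual(family_id=family_id, **kw)
        members.append(ind)
        return ind

    # a third generation needs >= 5 people (two founder couples collapse to
    # one); tiny requested sizes get two generations instead
    min_gen = 3 if target >= 5 else 2
    fa0 = add(person_id=new_id(), sex="male")
    mo0 = add(person_id=new_id(), sex="female")
    couples = [(fa0, mo0)]
    gen = 1  # generations built so far
    mz_placed = not want_mz
    while couples and (len(members) < target or gen < min_gen):
        children: list[Individual] = []
        for fa, mo in couples:
            n_kids = int(rng.integers(2, 6))
            for _ in range(n_kids):
                if children and len(members) >= target and gen + 1 >= min_gen:
                    break
                sex = "male" if rng.random() < 0.5 else "female"
                if not mz_placed:
                    twin_id = f"MZ{mz_counter + 1}"
                    for _t in range(2):
                        children.append(
                            add(
                                person_id=new_id(),
                                father_id=fa.person_id,
                                mother_id=mo.person_id,
                                sex=sex,
                                mz_group=twin_id,
                            )
                        )
                    mz_placed = True
                else:
                    children.append(
                        add(
                            person_id=new_id(),
                            father_id=fa.person_id,
                            mother_id=mo.person_id,
                            sex=sex,
                        )
                    )
        # marry in spouses for a subset of children; force one marriage while
        # the family still needs to grow in size or depth
        next_couples = []
        for i, child in enumerate(children):
            last = i == len(children) - 1
            force = last and not next_couples and (gen + 1 < min_gen or len(members) < target)
            if force or (len(members) < target and rng.random() < 0.55):
                spouse_sex = "female" if child.sex == "male" else "male"
                spouse = add(person_id=new_id(), sex=spouse_sex)
                pair = (child, spouse) if child.sex == "male" else (spouse, child)
                next_couples.append(pair)
        couples = next_couples
        gen += 1
    return members


# ---------------------------------------------------------------------------
# Additive relationship matrix


def additive_relationship(pedigrees: PedigreeSet) -> pd.DataFrame:
    """Additive (numerator) relationship matrix by the recursive tabular method.

    Members of an MZ group are collapsed to a single genome before the
    recursion and expanded afterwards, so twins get an off-diagonal entry
    equal to their diagonal entry and identical rows elsewhere.
    """
    order = pedigrees.topological_order()
    # map person -> genome (first-listed twin represents the pair)
    genome_of: dict[str, str] = {}
    for ind in order:
        if ind.mz_group is not None:
            rep = min(m.person_id for m in pedigrees.mz_groups()[ind.mz_group])
            genome_of[ind.person_id] = rep
        else:
            genome_of[ind.person_id] = ind.person_id
    genomes: list[str] = []
    seen = set()
    for ind in order:
        g = genome_of[ind.person_id]
        if g not in seen:
            seen.add(g)
            genomes.append(g)
    gidx = {g: i for i, g in enumerate(genomes)}
    m = len(genomes)
    A = np.zeros((m, m))
    for ind in order:
        g = genome_of[ind.person_id]
        i = gidx[g]
        if ind.person_id != g:
            continue  # second twin: same genome, already filled
        if ind.is_founder:
            A[i, i] = 1.0
        else:
            fi = gidx[genome_of[ind.father_id]]
            mi = gidx[genome_of[ind.mother_id]]
            A[i, i] = 1.0 + 0.5 * A[fi, mi]
            for j in range(m):
                if j == i:
                    continue
                if A[j, j] == 0.0:
                    continue  # not yet processed
                val = 0.5 * (A[j, fi] + A[j, mi])
                A[i, j] = A[j, i] = val
    ids = pedigrees.person_ids
    n = len(ids)
    full = np.empty((n, n))
    rows = [gidx[genome_of[p]] for p in ids]
    full[:] = A[np.ix_(rows, rows)]
    return pd.DataFrame(full, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# PED/FAM I/O (whitespace-delimited; 0 = missing parent; sex 1=male 2=female)

_SEX_OUT = {"male": "1", "female": "2"}
_SEX_IN = {"1": "male", "2": "female"}


def write_pedigree(pedigrees: PedigreeSet, path) -> None:
    """Write a PED/FAM file: family, person, father, mother, sex."""
    with open(path, "w") as fh:
        for ind in pedigrees.individuals:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.person_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                    ]
                )
                + "\n"
            )


def read_pedigree(path) -> PedigreeSet:
    """Read a PED/FAM file written by :func:`write_pedigree`.

    MZ groups are not representable in PED and are lost on round trip
    unless re-annotated.
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 5:
                raise PedigreeError(f"{path}:{lineno}: expected >= 5 columns")
            fam, pid, father, mother, sex = fields[:5]
            if sex not in _SEX_IN:
                raise PedigreeError(f"{path}:{lineno}: unknown sex code {sex!r}")
            individuals.append(
                Individual(
                    person_id=pid,
                    family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_IN[sex],
                )
            )
    return PedigreeSet(individuals)
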