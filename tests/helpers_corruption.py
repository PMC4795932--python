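"""Seed targeted conformance defects into a loaded store.

Each function mutates k randomly chosen records into one violation class
and returns the surrogate ids of the mutated records, so tests can check
the validator pinpoints every one. Corruptions bypass the API (and the
foreign-key pragma) on purpose: the validator must catch what the
constraints cannot.
"""

from __future__ import annotations

import random
from contextlib import contextmanager

from chadolite.store import Store


@contextmanager
def fk_off(store: Store):
    store.commit()
    store.execute("PRAGMA foreign_keys=OFF")
    yield
    store.commit()
    store.execute("PRAGMA foreign_keys=ON")


def _ids(store: Store, sql: str, params=()) -> list[int]:
    return [r[0] for r in store.execute(sql, params)]


def corrupt_dangling_term(store: Store, k: int, rng: random.Random) -> list[int]:
    ids = rng.sample(_ids(store, "SELECT featureprop_id FROM featureprop"), k)
    with fk_off(store):
        for i in ids:
            store.execute(
                "UPDATE featureprop SET type_id = 99999900 + ? "
                "WHERE featureprop_id = ?",
                (i, i),
            )
    return ids


def corrupt_phenotype_uniquename(store, k, rng) -> list[int]:
    ids = rng.sample(_ids(store, "SELECT phenotype_id FROM phenotype"), k)
    with fk_off(store):
        for i in ids:
            store.execute(
                "UPDATE phenotype SET uniquename = uniquename || '_X' "
                "WHERE phenotype_id = ?",
                (i,),
            )
    return ids


def corrupt_genotype_uniquename(store, k, rng) -> list[int]:
    ids = rng.sample(
        _ids(
            store,
            "SELECT genotype_id FROM genotype "
            "JOIN feature_genotype USING (genotype_id)",
        ),
        k,
    )
    with fk_off(store):
        for i in ids:
            store.execute(
                "UPDATE genotype SET uniquename = 'XX_' || uniquename "
                "WHERE genotype_id = ?",
                (i,),
            )
    return ids


def corrupt_primer_uniquename(store, k, rng) -> list[int]:
    ids = rng.sample(
        _ids(
            store,
            "SELECT f.feature_id FROM feature f "
            "JOIN cvterm t ON t.cvterm_id = f.type_id WHERE t.name = 'primer'",
        ),
        k,
    )
    with fk_off(store):
        for i in ids:
            store.execute(
                "UPDATE feature SET uniquename = 'zz' || uniquename "
                "WHERE feature_id = ?",
                (i,),
            )
    return ids


def corrupt_pedigree_cycle(store, k, rng) -> list[int]:
    rows = store.execute(
        "SELECT sr.subject_id, sr.object_id, sr.type_id "
        "FROM stock_relationship sr JOIN cvterm t ON t.cvterm_id = sr.type_id "
        "WHERE t.name LIKE '%_parent_of'"
    ).fetchall()
    picked = rng.sample(rows, k)
    new_ids = []
    with fk_off(store):
        for subject, obj, type_id in picked:
            cur = store.execute(
                "INSERT INTO stock_relationship "
                "(subject_id, object_id, type_id, rank) VALUES (?, ?, ?, 7)",
                (obj, subject, type_id),
            )
            new_ids.append(cur.lastrowid)
    return new_ids


def corrupt_missing_start(store, k, rng) -> list[int]:
    ids = rng.sample(_ids(store, "SELECT featurepos_id FROM featurepos"), k)
    with fk_off(store):
        for i in ids:
            store.execute(
                "DELETE FROM featureposprop WHERE featurepos_id = ? AND "
                "type_id IN (SELECT cvterm_id FROM cvterm WHERE name='start')",
                (i,),
            )
    return ids


def corrupt_featureloc_range(store, k, rng) -> list[int]:
    ids = rng.sample(
        _ids(store, "SELECT featureloc_id FROM featureloc WHERE fmax IS NOT NULL"),
        k,
    )
    with fk_off(store):
        for i in ids:
            store.execute(
                "UPDATE featureloc SET fmin = fmax + 5 WHERE featureloc_id = ?",
                (i,),
            )
    return ids


def corrupt_noncanonical_genotype(store, k, rng) -> list[int]:
    candidates = []
    for gid, desc in store.execute(
        "SELECT genotype_id, description FROM genotype "
        "WHERE description LIKE '%|%'"
    ):
        flipped = "|".join(sorted(desc.split("|"), reverse=True))
        if flipped != desc:
            candidates.append((gid, flipped))
    picked = rng.sample(candidates, k)
    with fk_off(store):
        for gid, flipped in picked:
            store.execute(
                "UPDATE genotype SET description = ? WHERE genotype_id = ?",
                (flipped, gid),
            )
    return [gid for gid, _ in picked]


def corrupt_relationship_type(store, k, rng) -> list[int]:
    bad_term = store.scalar(
        "SELECT cvterm_id FROM cvterm JOIN cv USING (cv_id) "
        "WHERE cv.name='local' AND cvterm.name='comments'"
    )
    # restrict to part_of edges so this class cannot mask a corrupted
    # primer's adjacent_to edge seeded by another class
    ids = rng.sample(
        _ids(
            store,
            "SELECT fr.feature_relationship_id FROM feature_relationship fr "
            "JOIN cvterm t ON t.cvterm_id = fr.type_id WHERE t.name='part_of'",
        ),
        k,
    )
    with fk_off(store):
        for i in ids:
            store.execute(
                "UPDATE feature_relationship SET type_id = ? "
                "WHERE feature_relationship_id = ?",
                (bad_term, i),
            )
    return ids


#: class name -> (seeding function, violation kind the validator must emit)
CORRUPTION_CLASSES = {
    "dangling_term": (corrupt_dangling_term, "dangling_fk"),
    "phenotype_uniquename": (
        corrupt_phenotype_uniquename,
        "bad_phenotype_uniquename",
    ),
    "genotype_uniquename": (
        corrupt_genotype_uniquename,
        "bad_genotype_uniquename",
    ),
    "primer_uniquename": (corrupt_primer_uniquename, "bad_primer_uniquename"),
    "pedigree_cycle": (corrupt_pedigree_cycle, "pedigree_cycle"),
    "missing_start": (corrupt_missing_start, "missing_start_prop"),
    "featureloc_range": (corrupt_featureloc_range, "bad_featureloc_range"),
    "noncanonical_genotype": (
        corrupt_noncanonical_genotype,
        "non_canonical_genotype",
    ),
    "relationship_type": (
        corrupt_relationship_type,
        "disallowed_relationship_type",
    ),
}
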