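import itertools

import pytest

from scfaprof import FixtureSpec, GenomeRecord, build_bpm, default_ruleset
from scfaprof.synthetic import generate_reference_collection

# printed variant-combination genome counts of the reference collection
BUTYRATE_COMBOS = [
    ("P1", 186), ("P1+P2", 41), ("P1+P3", 35), ("P1+P4", 28),
    ("P1+P2+P3", 8), ("P1+P2+P4", 16), ("P2+P4", 2), ("P1+P3+P4", 28),
    ("P1+P2+P3+P4", 8), ("P2", 5), ("P4", 2),
]
PROPIONATE_COMBOS = [
    ("P1", 447), ("P1+P2", 6), ("P1+P3", 96), ("P1+P2+P3", 2),
    ("P2", 64), ("P2+P3", 18), ("P3", 193),
]
LACTATE_COMBOS = [("L", 1153), ("D", 632), ("L+D", 655)]
N_COLLECTION = 2856
N_ACETATE = 2481
N_FORMATE = 2041


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def reference():
    return generate_reference_collection(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def reference_bpm(reference):
    return reference.bpm()


def roles_for_combination(ruleset, product, labels):
    """Union of first-alternative roles over the named variants."""
    roles = set()
    for d in ruleset.for_product(product):
        if d.variant_label in labels:
            for group in d.requirements:
                roles |= set(group.alternatives[0])
    return roles


def _expand(combo):
    return set(combo.split("+"))


@pytest.fixture(scope="session")
def collection_bpm(ruleset):
    """A genome collection realizing the printed variant-combination counts
    for all six products, evaluated through the rule engine."""
    def assignments(combos, total):
        out = []
        for combo, count in combos:
            out.extend([_expand(combo)] * count)
        out.extend([set()] * (total - len(out)))
        return out

    butyrate = assignments(BUTYRATE_COMBOS, N_COLLECTION)
    propionate = assignments(PROPIONATE_COMBOS, N_COLLECTION)
    lactate = assignments(LACTATE_COMBOS, N_COLLECTION)
    genomes = []
    for i in range(N_COLLECTION):
        roles = set()
        roles |= roles_for_combination(ruleset, "butyrate", butyrate[i])
        roles |= roles_for_combination(ruleset, "propionate", propionate[i])
        if i < N_ACETATE:
            roles |= roles_for_combination(ruleset, "acetate", {"A"})
        if i < N_FORMATE:
            roles |= roles_for_combination(ruleset, "formate", {"F"})
        if "L" in lactate[i]:
            roles |= roles_for_combination(ruleset, "L-lactate", {"L"})
        if "D" in lactate[i]:
            roles |= roles_for_combination(ruleset, "D-lactate", {"D"})
        taxonomy = (
            "PhylumA", "ClassA", "OrderA", f"Family{i % 40:02d}",
            f"Genus{i % 120:03d}", f"Species{i % 400:03d}", f"strain{i}",
        )
        genomes.append(GenomeRecord(f"G{i:04d}", taxonomy, frozenset(roles)))
    return build_bpm(genomes, ruleset)


def brute_force_calls(roles, ruleset):
    """Independent variant-call oracle: expand every variant's requirement
    sets as explicit role combinations and test subset inclusion."""
    roles = set(roles)
    calls = {p: set() for p in ruleset.products}
    for d in ruleset:
        groups = [g for g in d.requirements if g.required]
        complete = False
        for combo in itertools.product(*(g.alternatives for g in groups)):
            needed = set().union(*combo)
            if needed <= roles:
                complete = True
                break
        if complete:
            label = d.variant_label
            if d.sublabel is not None:
                g = d.requirements[d.sublabel.group]
                sat = {alt for alt in g.alternatives if set(alt) <= roles}
                if sat == {d.sublabel.sole_alternative}:
                    label = d.sublabel.label
            calls[d.product].add(label)
    return calls
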