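"""Symbolic MPT model structure and the EQN interchange format.

A multinomial processing tree (MPT) model expresses the probability of each
observable response category as a sum of branch probabilities, where every
branch is a product of transition probabilities::

    P(B_ik | theta) = c_ik * prod_s theta_s^a_iks * (1 - theta_s)^b_iks

``a_iks`` and ``b_iks`` count how often parameter ``theta_s`` and its
complement appear on the branch, and ``c_ik`` collects numeric constants.
Models are interchanged as EQN files: the first line is a comment, every
following non-blank line holds the tree label, the category label, and the
branch equation (a ``*``-separated product of ``p``, ``(1-p)``, or numbers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Branch",
    "MptModel",
    "RestrictionSet",
    "MptParseError",
    "MptStructureError",
    "parse_eqn",
    "parse_restrictions",
    "apply_restrictions",
    "within_subject_eqn",
    "validate_model",
    "serialize_eqn",
    "two_htsm_eqn",
    "two_htsm_restrictions",
]


class MptParseError(ValueError):
    """Raised for malformed EQN or restriction input."""


class MptStructureError(ValueError):
    """Raised when a parsed model violates MPT structural constraints."""


_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class Branch:
    """One processing path terminating in a response category."""

    tree_label: str
    category_label: str
    constant_c: float = 1.0
    exponents_a: dict[str, int] = field(default_factory=dict)
    exponents_b: dict[str, int] = field(default_factory=dict)

    def probability(self, theta: dict[str, float]) -> float:
        """Branch probability c * prod theta^a * (1-theta)^b."""
        p = self.constant_c
        for name, k in self.exponents_a.items():
            p *= theta[name] ** k
        for name, k in self.exponents_b.items():
            p *= (1.0 - theta[name]) ** k
        return p


@dataclass(frozen=True)
class MptModel:
    """A validated symbolic MPT model.

    Attributes
    ----------
    trees : ordered tree labels.
    categories : ordered (category_label, tree_label) pairs.
    branches : all branches, grouped implicitly by (tree, category).
    parameters : ordered free parameter names (S >= 1).
    """

    trees: tuple[str, ...]
    categories: tuple[tuple[str, str], ...]
    branches: tuple[Branch, ...]
    parameters: tuple[str, ...]

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def category_labels(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.categories)

    @property
    def tree_of_category(self) -> dict[str, str]:
        return dict(self.categories)

    @property
    def n_free_categories(self) -> int:
        """Free categories: K minus one simplex constraint per tree."""
        return len(self.categories) - len(self.trees)

    def category_probability(self, theta: dict[str, float], category: str) -> float:
        return sum(
            b.probability(theta) for b in self.branches if b.category_label == category
        )

    def category_probabilities_dict(self, theta: dict[str, float]) -> dict[str, float]:
        out = {c: 0.0 for c in self.category_labels}
        for b in self.branches:
            out[b.category_label] += b.probability(theta)
        return out


@dataclass(frozen=True)
class RestrictionSet:
    """Equality classes and constant bindings for MPT parameters.

    Each equality class collapses onto its first-listed name; constants fix
    a parameter to a value in (0, 1).
    """

    equality_classes: tuple[tuple[str, ...], ...] = ()
    constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls in self.equality_classes:
            for name in cls:
                if name in seen:
                    raise MptParseError(
                        f"parameter {name!r} appears in more than one restriction"
                    )
                seen.add(name)
        for name, value in self.constants.items():
            if name in seen and not any(
                name in cls for cls in self.equality_classes
            ):
                raise MptParseError(f"parameter {name!r} both equated and fixed")
            if not (0.0 < value < 1.0):
                raise MptParseError(
                    f"constant for {name!r} must lie in (0,1), got {value}"
                )


def _parse_equation(equation: str, line_no: int) -> tuple[float, dict[str, int], dict[str, int]]:
    """Split a branch equation into (constant, a-exponents, b-exponents)."""
    # normalize: allow '*' to be omitted around parentheses
    text = equation.replace(" ", "")
    text = re.sub(r"\)\(", ")*(", text)
    text = re.sub(r"\)(?=[A-Za-z0-9_.])", ")*", text)
    text = re.sub(r"(?<=[A-Za-z0-9_.])\(", "*(", text)
    const = 1.0
    ea: dict[str, int] = {}
    eb: dict[str, int] = {}
    for factor in text.split("*"):
        if not factor:
            raise MptParseError(f"line {line_no}: empty factor in {equation!r}")
        m = re.fullmatch(r"\(1-([^()]+)\)", factor)
        if m is not None:
            name = m.group(1)
            if _is_number(name):
                const *= 1.0 - float(name)
            elif _NAME_RE.fullmatch(name):
                eb[name] = eb.get(name, 0) + 1
            else:
                raise MptParseError(f"line {line_no}: malformed factor {factor!r}")
        elif _is_number(factor):
            const *= float(factor)
        elif _NAME_RE.fullmatch(factor):
            ea[factor] = ea.get(factor, 0) + 1
        else:
            raise MptParseError(f"line {line_no}: malformed factor {factor!r}")
    if not (0.0 < const <= 1.0):
        raise MptParseError(
            f"line {line_no}: branch constant {const} outside (0,1]"
        )
    return const, ea, eb


def parse_eqn(text: str) -> MptModel:
    """Parse EQN file content into an :class:`MptModel`.

    The first line is always skipped as a comment; ``#``-prefixed lines are
    skipped as well. Remaining non-blank lines must have at least three
    whitespace-separated fields: tree label, category label, equation
    (the equation may contain spaces).
    """
    lines = text.splitlines()
    branches: list[Branch] = []
    trees: list[str] = []
    categories: list[tuple[str, str]] = []
    params: set[str] = set()
    for line_no, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(None, 2)
        if len(fields) < 3:
            raise MptParseError(
                f"line {line_no}: expected 'tree category equation', got {raw!r}"
            )
        tree, category, equation = fields
        const, ea, eb = _parse_equation(equation, line_no)
        if tree not in trees:
            trees.append(tree)
        prior_tree = dict(categories).get(category)
        if prior_tree is None:
            categories.append((category, tree))
        elif prior_tree != tree:
            raise MptStructureError(
                f"line {line_no}: category {category!r} appears in trees "
                f"{prior_tree!r} and {tree!r}"
            )
        params.update(ea)
        params.update(eb)
        branches.append(
            Branch(tree, category, const, ea, eb)
        )
    if not branches:
        raise MptParseError("no branch lines found (first line is a comment)")
    if not params:
        raise MptStructureError("model contains no free parameters")
    model = MptModel(
        trees=tuple(trees),
        categories=tuple(categories),
        branches=tuple(branches),
        parameters=tuple(sorted(params)),
    )
    return model


def serialize_eqn(model: MptModel, comment: str = "generated") -> str:
    """Write a model back into EQN text (first line is the comment)."""
    lines = [comment]
    for b in model.branches:
        factors: list[str] = []
        if b.constant_c != 1.0:
            factors.append(repr(b.constant_c))
        for name in sorted(b.exponents_a):
            factors.extend([name] * b.exponents_a[name])
        for name in sorted(b.exponents_b):
            factors.extend([f"(1-{name})"] * b.exponents_b[name])
        if not factors:
            factors = ["1.0"]
        lines.append(f"{b.tree_label} {b.category_label} {'*'.join(factors)}")
    return "\n".join(lines) + "\n"


def parse_restrictions(source, model: MptModel | None = None) -> RestrictionSet:
    """Parse restriction chains ``p1 = p2 = ... [= const]``.

    ``source`` is either text (one chain per line) or a list of chain
    strings. A numeric right-most element fixes the whole chain to that
    constant. When ``model`` is given, parameter names are validated.
    """
    if isinstance(source, str):
        entries = [ln.strip() for ln in source.splitlines()]
    else:
        entries = [str(e).strip() for e in source]
    classes: list[tuple[str, ...]] = []
    constants: dict[str, float] = {}
    for entry in entries:
        if not entry or entry.startswith("#"):
            continue
        tokens = [t.strip() for t in entry.split("=")]
        if any(not t for t in tokens) or len(tokens) < 2:
            raise MptParseError(f"malformed restriction {entry!r}")
        numbers = [t for t in tokens if _is_number(t)]
        names = [t for t in tokens if not _is_number(t)]
        if len(set(numbers)) > 1:
            raise MptParseError(
                f"restriction {entry!r} fixes parameters to two different constants"
            )
        if numbers and _is_number(tokens[0]):
            raise MptParseError(
                f"restriction {entry!r}: constant must be the right-most element"
            )
        for name in names:
            if not _NAME_RE.fullmatch(name):
                raise MptParseError(f"invalid parameter name {name!r} in {entry!r}")
            if model is not None and name not in model.parameters:
                raise MptParseError(
                    f"unknown parameter {name!r}; model parameters are "
                    f"{list(model.parameters)}"
                )
        if numbers:
            value = float(numbers[0])
            for name in names:
                constants[name] = value
        else:
            classes.append(tuple(names))
    return RestrictionSet(tuple(classes), constants)


def apply_restrictions(model: MptModel, restrictions: RestrictionSet) -> MptModel:
    """Fold equality classes and constants into the model.

    Equated parameters are renamed to the first name of their class;
    constants are multiplied into each branch's ``c_ik``.
    """
    rename: dict[str, str] = {}
    for cls in restrictions.equality_classes:
        rep = cls[0]
        for name in cls:
            rename[name] = rep
    const_of: dict[str, float] = dict(restrictions.constants)
    for name in list(const_of):
        if name in rename:  # whole class fixed
            rep = rename[name]
            const_of.setdefault(rep, const_of[name])
    for name in set(rename) | set(const_of):
        if name not in model.parameters:
            raise MptParseError(
                f"restriction references unknown parameter {name!r}"
            )
    # a class whose representative is fixed propagates the constant
    fixed = {rename.get(n, n): v for n, v in const_of.items()}

    new_branches: list[Branch] = []
    params: set[str] = set()
    for b in model.branches:
        const = b.constant_c
        ea: dict[str, int] = {}
        eb: dict[str, int] = {}
        for name, k in b.exponents_a.items():
            tgt = rename.get(name, name)
            if tgt in fixed:
                const *= fixed[tgt] ** k
            else:
                ea[tgt] = ea.get(tgt, 0) + k
        for name, k in b.exponents_b.items():
            tgt = rename.get(name, name)
            if tgt in fixed:
                const *= (1.0 - fixed[tgt]) ** k
            else:
                eb[tgt] = eb.get(tgt, 0) + k
        params.update(ea)
        params.update(eb)
        new_branches.append(Branch(b.tree_label, b.category_label, const, ea, eb))
    if not params:
        raise MptStructureError(
            "restrictions removed every free parameter; nothing to estimate"
        )
    return MptModel(
        trees=model.trees,
        categories=model.categories,
        branches=tuple(new_branches),
        parameters=tuple(sorted(params)),
    )


def within_subject_eqn(
    model: MptModel,
    labels: list[str],
    constant_params: set[str] | None = None,
) -> MptModel:
    """Replicate the model once per within-subjects condition.

    Trees, categories and non-shared parameters receive a ``_<label>``
    suffix per condition; parameters in ``constant_params`` keep one shared
    name across all conditions.
    """
    constant_params = set(constant_params or ())
    if not labels:
        raise ValueError("labels must be nonempty")
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be distinct")
    unknown = constant_params - set(model.parameters)
    if unknown:
        raise MptParseError(f"unknown constant parameters: {sorted(unknown)}")

    existing = set(model.parameters)
    new_names = {
        f"{p}_{lab}"
        for p in model.parameters
        if p not in constant_params
        for lab in labels
    }
    clash = new_names & existing
    if clash:
        raise MptStructureError(f"suffixed names collide with existing: {sorted(clash)}")

    trees: list[str] = []
    categories: list[tuple[str, str]] = []
    branches: list[Branch] = []
    params: set[str] = set()

    def sfx(name: str, lab: str) -> str:
        return name if name in constant_params else f"{name}_{lab}"

    for lab in labels:
        for t in model.trees:
            trees.append(f"{t}_{lab}")
        for c, t in model.categories:
            categories.append((f"{c}_{lab}", f"{t}_{lab}"))
        for b in model.branches:
            ea = {sfx(n, lab): k for n, k in b.exponents_a.items()}
            eb = {sfx(n, lab): k for n, k in b.exponents_b.items()}
            params.update(ea)
            params.update(eb)
            branches.append(
                Branch(
                    f"{b.tree_label}_{lab}",
                    f"{b.category_label}_{lab}",
                    b.constant_c,
                    ea,
                    eb,
                )
            )
    return MptModel(
        trees=tuple(trees),
        categories=tuple(categories),
        branches=tuple(branches),
        parameters=tuple(sorted(params)),
    )


def validate_model(
    model: MptModel, n_random_theta: int = 10, seed: int = 0
) -> dict:
    """Numerical checks: per-tree simplex closure and identifiability rank.

    Evaluates the category probabilities at ``n_random_theta`` uniform
    parameter draws, reporting the maximal deviation of per-tree sums from 1
    and the numerical rank of the Jacobian of category probabilities with
    respect to the parameters (rank < S flags a non-identifiable model).
    """
    rng = np.random.default_rng(seed)
    S = model.n_parameters
    max_dev = 0.0
    ranks = []
    h = 1e-6
    for _ in range(n_random_theta):
        theta_vec = rng.uniform(0.05, 0.95, size=S)
        theta = dict(zip(model.parameters, theta_vec))
        probs = model.category_probabilities_dict(theta)
        for t in model.trees:
            s = sum(probs[c] for c, tc in model.categories if tc == t)
            max_dev = max(max_dev, abs(s - 1.0))
        jac = np.empty((len(model.categories), S))
        for j, name in enumerate(model.parameters):
            up = dict(theta)
            dn = dict(theta)
            up[name] += h
            dn[name] -= h
            pu = model.category_probabilities_dict(up)
            pd = model.category_probabilities_dict(dn)
            jac[:, j] = [
                (pu[c] - pd[c]) / (2 * h) for c, _ in model.categories
            ]
        ranks.append(int(np.linalg.matrix_rank(jac, tol=1e-6)))
    return {
        "max_simplex_deviation": max_dev,
        "jacobian_rank": int(max(ranks)) if ranks else 0,
        "n_parameters": S,
        "identified_numerically": bool(ranks and max(ranks) == S),
    }


# ---------------------------------------------------------------------------
# Bundled fixture: two-high-threshold source monitoring model (2HTSM)
# ---------------------------------------------------------------------------

def two_htsm_eqn() -> str:
    """EQN text for the two-high-threshold source-monitoring model.

    Three trees for items from the expected source (E), the unexpected
    source (U), and new items (N); nine response categories (three responses
    A/B/N per item type). Parameters: item detection D_1 (source A items),
    D_2 (source B), D_3 (new items); source memory d_1, d_2; source guessing
    a (after detection) and g (after guessing "old"); old/new guessing b.
    Tree and category labels (E/U/N, E_A ... N_N) are this package's
    convention for the standard model.
    """
    return "\n".join(
        [
            "# 2HTSM: two-high-threshold source monitoring",
            # Source A items (expected source), responses A/B/N
            "E E_A D_1*d_1",
            "E E_A D_1*(1-d_1)*a",
            "E E_A (1-D_1)*b*g",
            "E E_B D_1*(1-d_1)*(1-a)",
            "E E_B (1-D_1)*b*(1-g)",
            "E E_N (1-D_1)*(1-b)",
            # Source B items (unexpected source)
            "U U_B D_2*d_2",
            "U U_B D_2*(1-d_2)*(1-a)",
            "U U_B (1-D_2)*b*(1-g)",
            "U U_A D_2*(1-d_2)*a",
            "U U_A (1-D_2)*b*g",
            "U U_N (1-D_2)*(1-b)",
            # New items
            "N N_N D_3",
            "N N_N (1-D_3)*(1-b)",
            "N N_A (1-D_3)*b*g",
            "N N_B (1-D_3)*b*(1-g)",
        ]
    ) + "\n"


def two_htsm_restrictions() -> list[str]:
    """The identifying restrictions used with the 2HTSM: D_1=D_2=D_3, d_1=d_2, a=g."""
    return ["D_1 = D_2 = D_3", "d_1 = d_2", "a = g"]
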