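"""Reader/writer for the restricted OWL 2 functional-style dialect.

Supported constructs: ``Prefix``, ``Ontology``, ``Declaration(Class|
ObjectProperty)``, ``SubClassOf``, ``EquivalentClasses``, ``DisjointClasses``,
``SubObjectPropertyOf``, ``TransitiveObjectProperty``,
``ObjectPropertyDomain``, ``ObjectIntersectionOf``, ``ObjectSomeValuesFrom``,
``ObjectAllValuesFrom`` (guard position only), ``ObjectUnionOf`` (covering
position only), ``owl:Thing``, ``owl:Nothing``.  ``#`` starts a comment.

The grammar is small enough that a hand-written tokenizer and recursive
descent are simpler and give better error positions than a grammar library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import DialectSyntaxError
from .model import (
    BOT,
    TOP,
    Bottom,
    ClassExpression,
    Conjunction,
    CoveringDeclaration,
    DisjointClasses,
    EntityName,
    EquivalentClasses,
    Existential,
    GuardDeclaration,
    Named,
    Ontology,
    RoleDomain,
    SubClassOf,
    SubRoleOf,
    Top,
    TransitiveRole,
)

# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>[ \t\r\n]+)
  | (?P<comment>\#[^\n]*)
  | (?P<lpar>\() | (?P<rpar>\)) | (?P<eq>=)
  | (?P<iri><[^<>\s]*>)
  | (?P<name>[A-Za-z_][A-Za-z0-9_.\-]*(?::[A-Za-z0-9_.\-]*)?)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    kind: str  # lpar | rpar | eq | iri | name
    text: str
    line: int
    column: int


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    pos, line, line_start = 0, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DialectSyntaxError(
                f"unexpected character {text[pos]!r}", line, pos - line_start + 1
            )
        kind = m.lastgroup or ""
        value = m.group()
        if kind not in ("ws", "comment"):
            tokens.append(Token(kind, value, line, m.start() - line_start + 1))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            line_start = m.start() + value.rfind("\n") + 1
        pos = m.end()
    return tokens


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_AXIOM_KEYWORDS = {
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "SubObjectPropertyOf",
    "TransitiveObjectProperty",
    "ObjectPropertyDomain",
    "Declaration",
}


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    # -- token plumbing ------------------------------------------------------

    def _peek(self) -> Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self, expected: str) -> Token:
        tok = self._peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else Token("", "", 1, 1)
            raise DialectSyntaxError(
                f"unexpected end of input, expected {expected}", last.line, last.column
            )
        self.i += 1
        return tok

    def _expect(self, kind: str, expected: str) -> Token:
        tok = self._next(expected)
        if tok.kind != kind:
            raise DialectSyntaxError(
                f"expected {expected}, found {tok.text!r}", tok.line, tok.column
            )
        return tok

    def _expect_keyword(self, word: str) -> Token:
        tok = self._expect("name", word)
        if tok.text != word:
            raise DialectSyntaxError(
                f"expected {word}, found {tok.text!r}", tok.line, tok.column
            )
        return tok

    def _entity_name(self) -> EntityName:
        tok = self._expect("name", "a prefixed name")
        prefix, sep, local = tok.text.partition(":")
        if not sep or not local:
            raise DialectSyntaxError(
                f"expected prefix:Local name, found {tok.text!r}", tok.line, tok.column
            )
        return EntityName(prefix, local)

    # -- grammar -------------------------------------------------------------

    def document(self) -> Ontology:
        ont = Ontology(prefixes={})
        while (tok := self._peek()) is not None and tok.text == "Prefix":
            self._next("Prefix")
            self._expect("lpar", "'('")
            tag_tok = self._expect("name", "a prefix tag ending in ':'")
            if not tag_tok.text.endswith(":"):
                raise DialectSyntaxError(
                    f"prefix tag must end in ':', found {tag_tok.text!r}",
                    tag_tok.line,
                    tag_tok.column,
                )
            self._expect("eq", "'='")
            iri_tok = self._expect("iri", "an IRI in angle brackets")
            self._expect("rpar", "')'")
            ont.prefixes[tag_tok.text[:-1]] = iri_tok.text[1:-1]
        self._expect_keyword("Ontology")
        self._expect("lpar", "'('")
        if (tok := self._peek()) is not None and tok.kind == "iri":
            ont.iri = self._next("IRI").text[1:-1]
        while (tok := self._peek()) is not None and tok.kind != "rpar":
            self._item(ont)
        self._expect("rpar", "')'")
        if self._peek() is not None:
            tok = self._peek()
            assert tok is not None
            raise DialectSyntaxError(
                f"trailing content after Ontology(): {tok.text!r}", tok.line, tok.column
            )
        self._check_prefixes(ont)
        ont.validate()
        return ont

    def _check_prefixes(self, ont: Ontology) -> None:
        for n in sorted(ont.signature()):
            if n.prefix not in ont.prefixes and n.prefix != "owl":
                raise DialectSyntaxError(
                    f"prefix {n.prefix!r} of {n} is not declared in the header", 1, 1
                )

    def _item(self, ont: Ontology) -> None:
        tok = self._expect("name", "an axiom or declaration keyword")
        if tok.text not in _AXIOM_KEYWORDS:
            raise DialectSyntaxError(
                f"unsupported construct {tok.text!r}", tok.line, tok.column
            )
        self._expect("lpar", "'('")
        getattr(self, "_kw_" + tok.text)(ont, tok)
        self._expect("rpar", "')'")

    def _kw_Declaration(self, ont: Ontology, kw: Token) -> None:
        tok = self._expect("name", "Class or ObjectProperty")
        if tok.text not in ("Class", "ObjectProperty"):
            raise DialectSyntaxError(
                f"expected Class or ObjectProperty, found {tok.text!r}",
                tok.line,
                tok.column,
            )
        self._expect("lpar", "'('")
        n = self._entity_name()
        self._expect("rpar", "')'")
        if tok.text == "Class":
            ont.classes.add(n)
        else:
            ont.roles.add(n)

    def _kw_SubClassOf(self, ont: Ontology, kw: Token) -> None:
        sub = self._class_expression(allow_universal=False)
        # universal restriction is legal only as the whole superclass: a guard
        tok = self._peek()
        if tok is not None and tok.text == "ObjectAllValuesFrom":
            if not isinstance(sub, Named):
                raise DialectSyntaxError(
                    "guard axioms need a named subclass", tok.line, tok.column
                )
            self._next("ObjectAllValuesFrom")
            self._expect("lpar", "'('")
            role = self._entity_name()
            filler = self._class_expression(allow_universal=False)
            self._expect("rpar", "')'")
            if not isinstance(filler, Named):
                raise DialectSyntaxError(
                    "guard fillers must be named classes", tok.line, tok.column
                )
            ont.guards.append(GuardDeclaration(sub, role, filler))
            return
        sup = self._class_expression(allow_universal=False)
        ont.axioms.append(SubClassOf(sub, sup))

    def _kw_EquivalentClasses(self, ont: Ontology, kw: Token) -> None:
        exprs: list[ClassExpression] = [self._class_expression(allow_universal=False)]
        # a union is legal only as the second operand of a covering declaration
        tok = self._peek()
        if tok is not None and tok.text == "ObjectUnionOf":
            if not isinstance(exprs[0], Named):
                raise DialectSyntaxError(
                    "covering declarations need a named covered class",
                    tok.line,
                    tok.column,
                )
            self._next("ObjectUnionOf")
            self._expect("lpar", "'('")
            disjuncts: list[Named] = []
            while (t := self._peek()) is not None and t.kind != "rpar":
                d = self._class_expression(allow_universal=False)
                if not isinstance(d, Named):
                    raise DialectSyntaxError(
                        "covering disjuncts must be named classes", t.line, t.column
                    )
                disjuncts.append(d)
            self._expect("rpar", "')'")
            if len(disjuncts) < 2:
                raise DialectSyntaxError(
                    "covering needs at least two disjuncts", kw.line, kw.column
                )
            ont.covering.append(CoveringDeclaration(exprs[0], tuple(disjuncts)))
            return
        while (t := self._peek()) is not None and t.kind != "rpar":
            exprs.append(self._class_expression(allow_universal=False))
        if len(exprs) < 2:
            raise DialectSyntaxError(
                "EquivalentClasses needs at least two expressions", kw.line, kw.column
            )
        ont.axioms.append(EquivalentClasses(tuple(exprs)))

    def _kw_DisjointClasses(self, ont: Ontology, kw: Token) -> None:
        names: list[Named] = []
        while (t := self._peek()) is not None and t.kind != "rpar":
            e = self._class_expression(allow_universal=False)
            if not isinstance(e, Named):
                raise DialectSyntaxError(
                    "DisjointClasses takes named classes only", t.line, t.column
                )
            names.append(e)
        if len(names) < 2:
            raise DialectSyntaxError(
                "DisjointClasses needs at least two classes", kw.line, kw.column
            )
        ont.axioms.append(DisjointClasses(tuple(names)))

    def _kw_SubObjectPropertyOf(self, ont: Ontology, kw: Token) -> None:
        sub = self._entity_name()
        sup = self._entity_name()
        ont.axioms.append(SubRoleOf(sub, sup))

    def _kw_TransitiveObjectProperty(self, ont: Ontology, kw: Token) -> None:
        ont.axioms.append(TransitiveRole(self._entity_name()))

    def _kw_ObjectPropertyDomain(self, ont: Ontology, kw: Token) -> None:
        role = self._entity_name()
        tok = self._peek()
        domain = self._class_expression(allow_universal=False)
        if not isinstance(domain, Named):
            assert tok is not None
            raise DialectSyntaxError(
                "role domains must be named classes", tok.line, tok.column
            )
        ont.axioms.append(RoleDomain(role, domain))

    def _class_expression(self, allow_universal: bool) -> ClassExpression:
        tok = self._expect("name", "a class expression")
        if tok.text == "owl:Thing":
            return Top()
        if tok.text == "owl:Nothing":
            return Bottom()
        if tok.text == "ObjectIntersectionOf":
            self._expect("lpar", "'('")
            operands: list[ClassExpression] = []
            while (t := self._peek()) is not None and t.kind != "rpar":
                operands.append(self._class_expression(allow_universal=False))
            self._expect("rpar", "')'")
            if len(operands) < 2:
                raise DialectSyntaxError(
                    "ObjectIntersectionOf needs at least two operands",
                    tok.line,
                    tok.column,
                )
            return Conjunction(tuple(operands))
        if tok.text == "ObjectSomeValuesFrom":
            self._expect("lpar", "'('")
            role = self._entity_name()
            filler = self._class_expression(allow_universal=False)
            self._expect("rpar", "')'")
            return Existential(role, filler)
        if tok.text in ("ObjectAllValuesFrom", "ObjectUnionOf"):
            raise DialectSyntaxError(
                f"{tok.text} is not allowed in this position", tok.line, tok.column
            )
        prefix, sep, local = tok.text.partition(":")
        if not sep or not local:
            raise DialectSyntaxError(
                f"expected a class expression, found {tok.text!r}", tok.line, tok.column
            )
        return Named(EntityName(prefix, local))


def parse_ontology(text: str) -> Ontology:
    """Parse a dialect document into an :class:`Ontology`.

    Axiom order follows document order; guard and covering declarations are
    routed to their dedicated lists.  Raises :class:`DialectSyntaxError` with
    line/column on malformed input and :class:`UndeclaredNameError` when an
    axiom uses an undeclared name.
    """
    return _Parser(tokenize(text)).document()


# ---------------------------------------------------------------------------
# Serializer
# ---------------------------------------------------------------------------


def _render_expr(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return str(expr.name)
    if isinstance(expr, Top):
        return "owl:Thing"
    if isinstance(expr, Bottom):
        return "owl:Nothing"
    if isinstance(expr, Conjunction):
        return "ObjectIntersectionOf(" + " ".join(_render_expr(o) for o in expr.operands) + ")"
    if isinstance(expr, Existential):
        return f"ObjectSomeValuesFrom({expr.role} {_render_expr(expr.filler)})"
    raise TypeError(f"cannot serialize {expr!r}")


def _render_axiom(ax) -> str:
    if isinstance(ax, SubClassOf):
        return f"SubClassOf({_render_expr(ax.sub)} {_render_expr(ax.sup)})"
    if isinstance(ax, EquivalentClasses):
        return "EquivalentClasses(" + " ".join(_render_expr(e) for e in ax.exprs) + ")"
    if isinstance(ax, DisjointClasses):
        return "DisjointClasses(" + " ".join(str(n.name) for n in ax.names) + ")"
    if isinstance(ax, SubRoleOf):
        return f"SubObjectPropertyOf({ax.sub} {ax.sup})"
    if isinstance(ax, TransitiveRole):
        return f"TransitiveObjectProperty({ax.role})"
    if isinstance(ax, RoleDomain):
        return f"ObjectPropertyDomain({ax.role} {ax.domain.name})"
    raise TypeError(f"cannot serialize {ax!r}")


def serialize_ontology(ont: Ontology) -> str:
    """Write an :class:`Ontology` as a dialect document.

    Output is deterministic: prefixes sorted by tag, declarations sorted by
    name, axioms in insertion order, then guards, then coverings.
    ``parse_ontology(serialize_ontology(o))`` is structurally identical to
    ``o``.
    """
    lines: list[str] = []
    for tag in sorted(ont.prefixes):
        lines.append(f"Prefix({tag}:=<{ont.prefixes[tag]}>)")
    lines.append(f"Ontology(<{ont.iri}>")
    for n in sorted(ont.classes):
        lines.append(f"Declaration(Class({n}))")
    for n in sorted(ont.roles):
        lines.append(f"Declaration(ObjectProperty({n}))")
    for ax in ont.axioms:
        lines.append(_render_axiom(ax))
    for g in ont.guards:
        lines.append(
            f"SubClassOf({g.subject.name} ObjectAllValuesFrom({g.role} {g.filler.name}))"
        )
    for c in ont.covering:
        lines.append(
            f"EquivalentClasses({c.covered.name} ObjectUnionOf("
            + " ".join(str(d.name) for d in c.disjuncts)
            + "))"
        )
    lines.append(")")
    return "\n".join(lines) + "\n"
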