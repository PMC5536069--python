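"""Bundled reference sequences for the SNARE hydrophobic-anchor analysis.

Full-length mouse synaptobrevin 2 (VAMP2, UniProt P63044) and syntaxin 1A
(STX1A, UniProt O35526), plus ready-made segments for their C-terminal
hydrophobic membrane anchors: the last 22 residues of synaptobrevin 2 (one
cysteine, one glycine) and the last 23 residues of syntaxin 1A (tandem
cysteines, four glycines).  Both C-termini are assumed charge-neutralised
so the anchors can reside between the membrane leaflets.
"""

from __future__ import annotations

from .propensity import PeptideSegment, extract_cterminal_segment

__all__ = [
    "MOUSE_SYB2",
    "MOUSE_SYX1A",
    "SYB2_CTERM_N",
    "SYX1A_CTERM_N",
    "syb2_cterminal_segment",
    "syx1a_cterminal_segment",
]

# Mouse synaptobrevin 2 / VAMP2, UniProt P63044 (116 aa).
MOUSE_SYB2 = (
    "MSATAATAPPAAPAGEGGPPAPPPNLTSNRRLQQTQAQVDEVVDIMRVNVDKVLERDQKL"
    "SELDDRADALQAGASQFETSAAKLKRKYWWKNLKMMIILGVICAIILIIIIVYFST"
)

# Mouse syntaxin 1A, UniProt O35526 (288 aa).
MOUSE_SYX1A = (
    "MKDRTQELRTAKDSDDDDDVTVTVDRDRFMDEFFEQVEEIRGFIDKIAENVEEVKRKHSA"
    "ILASPNPDEKTKEELEELMSDIKKTANKVRSKLKSIEQSIEQEEGLNRSSADLRIRKTQH"
    "STLSRKFVEVMSEYNATQSDYRERCKGRIQRQLEITGRTTTSEELEDMLESGNPAIFASG"
    "IIMDSSISKQALSEIETRHSEIIKLENSIRELHDMFMDMAMLVESQGEMIDRIEYNVEHA"
    "VDYVERAVSDTKKAVKYQSKARRKKIMIIICCVILGIIIASTIGGIFG"
)

#: Lengths of the C-terminal hydrophobic anchors used throughout.
SYB2_CTERM_N = 22
SYX1A_CTERM_N = 23


def syb2_cterminal_segment() -> PeptideSegment:
    """The 22-residue C-terminal hydrophobic anchor of mouse synaptobrevin 2."""
    return extract_cterminal_segment(
        MOUSE_SYB2,
        SYB2_CTERM_N,
        "syb2-ct22",
        source_protein="mouse synaptobrevin 2 (VAMP2, UniProt P63044)",
        c_terminal_charge_neutralized=True,
    )


def syx1a_cterminal_segment() -> PeptideSegment:
    """The 23-residue C-terminal hydrophobic anchor of mouse syntaxin 1A."""
    return extract_cterminal_segment(
        MOUSE_SYX1A,
        SYX1A_CTERM_N,
        "syx1a-ct23",
        source_protein="mouse syntaxin 1A (UniProt O35526)",
        c_terminal_charge_neutralized=True,
    )
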