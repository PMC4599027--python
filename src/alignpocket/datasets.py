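"""Small bundled example datasets (plain text, typed from the literature).

Only one dataset ships with the package: the published profile-HMM E-value
panel used to classify the divergent *Diplonema papillatum* RNA ligase
candidate (DpRNL).  Seven DNA/RNA-ligase family models were searched against
DpRNL, the *Naegleria gruberi* ligase, and the two *Trypanosoma brucei*
editing ligases; dashes mark searches that returned no significant hit.
"""

from __future__ import annotations

from .family import EvalueTable, read_evalue_table

#: Families x proteins E-value panel for the divergent RNA ligase screen.
#: Column "DpRNL" is the candidate; "TbREL1"/"TbREL2" are the positive
#: controls and "NgRNL" the heterolobosean outgroup ligase.
LIGASE_EVALUE_PANEL_TSV = """\
family	model	DpRNL	NgRNL	TbREL1	TbREL2
DNA ligase ATP-dependent	PF01068	3.30e-5	2.60e-5	1.00e-3	1.60e-6
DNA ligase NAD-dependent	PF01653	2.20e-2	2.90e-2	-	4.70e-1
RNA ligase 1 defense/splicing	PF09511	2.70e-1	1.30e-2	3.40e-1	4.00e-1
RNA ligase 2 editing	PF09414	4.90e-12	3.20e-9	7.90e-55	4.30e-53
Capping enzyme	PF01331	2.70e-1	1.70e-1	9.10e-3	2.10e-1
LigT phosphoesterase	PF02834	-	-	-	-
RtcB splicing	PF01139	-	-	4.80e-1	-
"""


def ligase_evalue_panel() -> EvalueTable:
    """The RNA-ligase classification panel as an :class:`EvalueTable`."""
    return read_evalue_table(LIGASE_EVALUE_PANEL_TSV)
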