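# Protonation-state rules applied by the molecule "wash" after metal
# disconnection and largest-organic-fragment selection.  The first atom of
# each SMARTS match is the atom whose charge/hydrogen count is changed.
# Editing this file changes standardization behaviour; no code change needed.
version: 1
deprotonate:   # strong acids -> anionic form
  - name: carboxylic-acid
    smarts: "[OX2H1][CX3]=[OX1]"
  - name: sulfonic-acid
    smarts: "[OX2H1][SX4](=[OX1])=[OX1]"
  - name: phosphonic-or-phosphoric-acid
    smarts: "[OX2H1][PX4]=[OX1]"
protonate:     # strong bases -> cationic form
  - name: aliphatic-amine
    smarts: "[NX3;+0;!$([NX3]-[a]);!$([NX3]-[#6]=[O,N,S]);!$([NX3]-[!#6;!#1])]"
  - name: amidine-or-guanidine-imine-nitrogen
    smarts: "[NX2;+0;!a;$([NX2]=[CX3]-[NX3])]"
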