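# Generalized pharmacophore atom typing for the CATS topological descriptor.
# An atom receives a type if ANY of the type's SMARTS patterns matches it
# (first atom of the match).  Types are not exclusive: one atom may carry
# several labels (e.g. a hydroxyl oxygen is both donor and acceptor).
# The canonical type order below fixes the pair-index layout of the vector.
version: 1
type_order: [D, A, P, N, H, R]
types:
  D:   # hydrogen-bond donor: O or N bearing at least one hydrogen
    - "[#8;!H0]"
    - "[#7;!H0]"
  A:   # hydrogen-bond acceptor: any O; N that is neutral/anionic and has an
       # available lone pair (pyrrole-type aromatic NH excluded)
    - "[#8]"
    - "[#7;!+;!$([nH])]"
  P:   # positively charged, or a nitrogen basic enough to protonate
    - "[*;+]"
    - "[NX3;+0;!$([NX3]-[a]);!$([NX3]-[#6]=[O,N,S]);!$([NX3]-[!#6;!#1])]"
    - "[NX2;+0;!a;$([NX2]=[CX3]-[NX3])]"
  N:   # negatively charged, or a strongly acidic hydroxyl
    - "[*;-]"
    - "[OX2H1;$([OX2H1]-[CX3]=[OX1])]"
    - "[OX2H1;$([OX2H1]-[SX4](=[OX1])=[OX1])]"
    - "[OX2H1;$([OX2H1]-[PX4]=[OX1])]"
  H:   # hydrophobe: carbon, or halogen, surrounded only by C/H/halogen
    - "[#6;!$([#6]~[!#6;!#1;!#9;!#17;!#35;!#53])]"
    - "[F,Cl,Br,I;!$([F,Cl,Br,I]~[!#6;!#1])]"
  R:   # aromatic ring atom
    - "[a]"
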