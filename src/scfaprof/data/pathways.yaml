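# Default SCFA / lactate pathway rules for the human gut microbiome reference
# collection. Six fermentation products; butyrate and propionate each have
# several variants distinguished by their metabolic precursor.
#
# Grammar: a variant is complete in a genome iff every one of its role groups
# (own groups plus referenced shared segments) is satisfied. A group is an
# OR over alternatives; an alternative is a single functional role or a
# conjunction of roles joined with "+" (all members required). Groups may
# carry `required: false`, in which case they are annotated but never block
# a call.

roles:
  # Butyrate, acetyl-CoA route (P1): acetyl-CoA -> acetoacetyl-CoA -> crotonyl-CoA
  Thl:       {ec: "2.3.1.9",  description: "Acetyl-CoA acetyltransferase (thiolase)"}
  Hbd:       {ec: "1.1.1.157", description: "3-hydroxybutyryl-CoA dehydrogenase"}
  Crt:       {ec: "4.2.1.55", description: "3-hydroxybutyryl-CoA dehydratase (crotonase)"}
  # Butyrate, succinate route (P2)
  AldD:      {ec: "", description: "CoA-dependent succinate-semialdehyde dehydrogenase"}
  AbfH:      {ec: "", description: "NAD-dependent 4-hydroxybutyrate dehydrogenase"}
  Cat:       {ec: "", description: "4-hydroxybutyrate CoA-transferase"}
  AbfD:      {ec: "", description: "4-hydroxybutyryl-CoA dehydratase"}
  # Butyrate, glutamate route (P3)
  GctAB:     {ec: "", description: "Glutaconate CoA-transferase"}
  HgdABC:    {ec: "", description: "2-hydroxyglutaryl-CoA dehydratase"}
  GcdABC:    {ec: "", description: "Glutaconyl-CoA decarboxylase"}
  # Butyrate, lysine route (P4)
  KamA:      {ec: "", description: "Lysine 2,3-aminomutase"}
  KamDE:     {ec: "", description: "beta-lysine 5,6-aminomutase"}
  KDD:       {ec: "", description: "3,5-diaminohexanoate dehydrogenase"}
  KCE:       {ec: "", description: "3-keto-5-aminohexanoate cleavage enzyme"}
  KAL:       {ec: "", description: "3-aminobutyryl-CoA ammonia lyase"}
  # Butyrate, universal crotonyl-CoA -> butyryl-CoA step and terminal release
  Bcd-EtfAB: {ec: "", description: "Butyryl-CoA dehydrogenase / electron-transfer flavoprotein complex"}
  But:       {ec: "", description: "Butyryl-CoA:acetate CoA-transferase"}
  CtfAB:     {ec: "", description: "Butyryl-CoA transferase (two-subunit)"}
  Ptb:       {ec: "2.3.1.19", description: "Phosphate butyryltransferase"}
  Buk:       {ec: "2.7.2.7",  description: "Butyrate kinase"}
  # Propionate, succinate route (P1)
  PST:       {ec: "", description: "Propionyl-CoA:succinate CoA-transferase"}
  AarC:      {ec: "", description: "Succinyl-CoA:acetate CoA-transferase (AarC-type)"}
  MutAB:     {ec: "5.4.99.2", description: "Methylmalonyl-CoA mutase, fused-domain two-subunit form"}
  MutA2:     {ec: "", description: "Methylmalonyl-CoA mutase, catalytic subunit (split form)"}
  MutC:      {ec: "", description: "Methylmalonyl-CoA mutase, B12-binding subunit (split form)"}
  MutB2:     {ec: "", description: "Accessory GTPase of the split methylmalonyl-CoA mutase (COG1703)", annotation_only: true}
  Mce:       {ec: "5.1.99.1", description: "Methylmalonyl-CoA epimerase"}
  MmdABCDE:  {ec: "", description: "Methylmalonyl-CoA decarboxylase, multi-subunit complex"}
  Mmd:       {ec: "", description: "Methylmalonyl-CoA decarboxylase, single-subunit form"}
  MMCT:      {ec: "2.1.3.1", description: "Methylmalonyl-CoA carboxyltransferase (transcarboxylase, 5S/12S)"}
  # Propionate, lactate/acrylate route (P2)
  Pct:       {ec: "", description: "Propionate CoA-transferase"}
  LcdABC:    {ec: "", description: "Lactoyl-CoA dehydratase, three-subunit"}
  LcdX:      {ec: "4.2.1.54", description: "Lactoyl-CoA dehydratase, crotonase-superfamily form"}
  Acr:       {ec: "", description: "Acryloyl-CoA reductase"}
  # Propionate, propanediol route (P3)
  PduCDE:    {ec: "4.2.1.28", description: "Propanediol dehydratase, B12-dependent three-subunit"}
  PduC2:     {ec: "", description: "Propanediol dehydratase, B12-independent glycyl-radical form"}
  PduD2:     {ec: "", description: "PduC2 activating enzyme (radical SAM)"}
  PduP:      {ec: "", description: "Propionaldehyde dehydrogenase (CoA-acylating)"}
  PduL:      {ec: "", description: "Phosphate propanoyltransferase"}
  PduW:      {ec: "", description: "Propionate kinase"}
  # Acetate / formate / lactate
  Pta:       {ec: "2.3.1.8", description: "Phosphate acetyltransferase"}
  AckA:      {ec: "2.7.2.1", description: "Acetate kinase"}
  PflB:      {ec: "2.3.1.54", description: "Pyruvate formate-lyase"}
  PflA:      {ec: "", description: "Pyruvate formate-lyase activating enzyme (radical SAM)"}
  L-LDH:     {ec: "1.1.1.27", description: "L-lactate dehydrogenase"}
  D-LDH:     {ec: "1.1.1.28", description: "D-lactate dehydrogenase"}

products:
  butyrate:
    shared:
      universal:
        - [Bcd-EtfAB]
      terminal:
        - [But, CtfAB, Ptb+Buk]
    variants:
      P1:
        groups: [[Thl], [Hbd], [Crt]]
        shared: [universal, terminal]
      P2:
        groups: [[AldD], [AbfH], [Cat], [AbfD]]
        shared: [universal, terminal]
      P3:
        groups: [[GctAB], [HgdABC], [GcdABC]]
        shared: [universal, terminal]
      P4:
        groups: [[KamA], [KamDE], [KDD], [KCE], [KAL]]
        shared: [universal, terminal]
  propionate:
    variants:
      P1:
        groups:
          - alternatives: [PST, AarC]
            name: coa_transferase
          - [MutAB, MutA2+MutC]
          - [Mce]
          - [MmdABCDE, Mmd, MMCT]
      P2:
        groups: [[Pct], [LcdABC, LcdX], [Acr]]
      P3:
        groups: [[PduCDE, PduC2+PduD2], [PduP], [PduL], [PduW]]
        sublabel: {label: "P3*", group: 0, sole_alternative: PduC2+PduD2}
  acetate:
    variants:
      A:
        groups: [[Pta], [AckA]]
  formate:
    variants:
      F:
        groups: [[PflB], [PflA]]
  L-lactate:
    variants:
      L:
        groups: [[L-LDH]]
  D-lactate:
    variants:
      D:
        groups: [[D-LDH]]
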