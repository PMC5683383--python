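id: rna-extraction-ft
document:
  title: Extraction of total RNA from fresh/frozen tissue (FT)
  authors:
  - name: Kim M. Linton
    roles:
    - author
  - name: Yvonne Hey
    roles:
    - author
  - name: Sian Dibben
    roles:
    - author
  - name: Crispin J. Miller
    roles:
    - author
  - name: Anthony J. Freemont
    roles:
    - author
  - name: John A. Radford
    roles:
    - author
  - name: Stuart D. Pepper
    roles:
    - author
  protocol_identifier: DOI:10.2144/000113260
  application: Methods comparison for high-resolution transcriptional analysis of archival material on
    Affymetrix Plus 2.0 and Exon1.0 microarrays
  provenance: The extraction method (steps 2–21) is taken from the method supplied with TRIzol reagent
    Invitrogen, Paisley, UK).
  objective: Extraction of total RNA from fresh/frozen tumor tissue for high-resolution transcriptional
    analysis.
  specimens:
  - name: tumor tissue
    anatomical_part: tissues
  reagents:
  - name: Chloroform
    manufacturer: Sigma-Aldrich
  - name: Ethyl alcohol
    manufacturer: Sigma-Aldrich
  - name: Isopropyl alcohol
    manufacturer: Sigma-Aldrich
  - name: TRIzol
    manufacturer: Invitrogen
  equipment:
  - name: Forceps
    category: instrument
  - name: Homogenizer blades
    category: instrument
  - name: Scalpel
    category: instrument
  - name: Scalpel holder
    category: instrument
  - name: Tissue storage container
    category: consumable
  recipes:
  - name: Cleaning process of equipment
    text: 'Clean all RNA-work equipment before extraction: wash in Neutracon solution, rinse in 1% SDS
      made with nuclease-free water, rinse in 100% ethanol and air-dry.'
workflow:
  procedures:
  - id: lab procedure 1
    label: Protocol overview
    inputs:
    - tumor tissue
    outputs:
    - homogenized tissue
    steps:
    - id: lab subprocedure 1.1
      text: Recover tumor tissue at the time of surgery, trim into 1-cm3 fragments, and immerse immediately
        in TRIzol reagent prior to freezing at −80°.
      participants:
      - TRIzol
      - tumor tissue
    - id: lab subprocedure 1.2
      text: Thaw and weigh tissue prior to RNA extraction, working quickly.
      preceded_by: lab subprocedure 1.1
    - id: lab subprocedure 1.3
      text: Use a tissue power homogenizer (or a mortar and pestle) to homogenize tissue by hand.
      preceded_by: lab subprocedure 1.2
  - id: lab procedure 2
    label: 'Prior to RNA extraction: cleaning process of equipment'
    kind: recipe_execution
    preceded_by: lab procedure 1
    steps:
    - id: lab subprocedure 2.1
      text: Autoclave or wash equipment (i.e., tissue storage container, homogenizer blades, forceps,
        scalpel holder) in Neutracon solution for 2–4 h.
    - id: lab subprocedure 2.2
      text: Rinse equipment well in 1% SDS (prepared using DEPC-treated or other nuclease-free water).
      preceded_by: lab subprocedure 2.1
    - id: lab subprocedure 2.3
      text: Rinse in 100% ethanol and leave to air-dry.
      preceded_by: lab subprocedure 2.2
  - id: lab procedure 3
    label: RNA extraction
    preceded_by: lab procedure 2
    inputs:
    - homogenized tissue
    outputs:
    - name: RNA
      external_ref: chebi:RNA
    steps:
    - id: lab subprocedure 3.1
      text: Homogenize sample using tissue homogenizer.
    - id: lab subprocedure 3.2
      text: Add 0.2 mL chloroform per 1 mL TRIzol and cap tube tightly.
      preceded_by: lab subprocedure 3.1
      participants:
      - name: Chloroform
        measure:
          value: 0.2
          unit: mL
      - name: TRIzol
        measure:
          value: 1.0
          unit: mL
    - id: lab subprocedure 3.3
      text: Add 0.5 mL isopropyl alcohol per 1 mL TRIzol.
      preceded_by: lab subprocedure 3.2
      participants:
      - name: Isopropyl alcohol
        measure:
          value: 0.5
          unit: mL
    - id: lab subprocedure 3.4
      text: Add 1 mL 75% ethanol per 1 mL TRIzol and vortex for 10 s.
      preceded_by: lab subprocedure 3.3
    - id: step-05
      text: unprinted step from TRIzol method
      preceded_by: lab subprocedure 3.4
    - id: step-06
      text: unprinted step from TRIzol method
      preceded_by: step-05
    - id: step-07
      text: unprinted step from TRIzol method
      preceded_by: step-06
    - id: step-08
      text: unprinted step from TRIzol method
      preceded_by: step-07
    - id: step-09
      text: unprinted step from TRIzol method
      preceded_by: step-08
    - id: step-10
      text: unprinted step from TRIzol method
      preceded_by: step-09
    - id: step-11
      text: unprinted step from TRIzol method
      preceded_by: step-10
    - id: step-12
      text: unprinted step from TRIzol method
      preceded_by: step-11
    - id: step-13
      text: unprinted step from TRIzol method
      preceded_by: step-12
    - id: step-14
      text: unprinted step from TRIzol method
      preceded_by: step-13
    - id: step-15
      text: unprinted step from TRIzol method
      preceded_by: step-14
    - id: step-16
      text: unprinted step from TRIzol method
      preceded_by: step-15
    - id: step-17
      text: unprinted step from TRIzol method
      preceded_by: step-16
    - id: step-18
      text: unprinted step from TRIzol method
      preceded_by: step-17
    - id: step-19
      text: unprinted step from TRIzol method
      preceded_by: step-18
    - id: step-20
      text: unprinted step from TRIzol method
      preceded_by: step-19
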