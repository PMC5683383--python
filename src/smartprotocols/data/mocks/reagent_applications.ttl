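# Synthetic mock linked-data graph: reagent -> recorded applications.
# Local stand-in with the same join shape as a ChEBI-style application lookup.
@prefix ld: <https://w3id.org/smart-protocols/mock#> .

ld:app-bromophenol-blue
    ld:reagent-name "Bromophenol blue" ;
    ld:application "tracking dye for nucleic acid gel electrophoresis" .

ld:app-trizol
    ld:reagent-name "TRIzol" ;
    ld:application "isolation of total RNA from cells and tissues" .

ld:app-glucose
    ld:reagent-name "Glucose" ;
    ld:application "carbon source in microbial growth media" .

ld:app-chloroform
    ld:reagent-name "Chloroform" ;
    ld:application "phase separation in nucleic acid extraction" .
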