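# Synthetic mock linked-data graph: reagent -> diseases it can cause.
# Local stand-in with the same join shape as a SNOMED-style
# causative-agent-of lookup.
@prefix ld: <https://w3id.org/smart-protocols/mock#> .

ld:hazard-chloroform-liver
    ld:reagent-name "Chloroform" ;
    ld:causes-disease "toxic liver disease" .

ld:hazard-chloroform-cns
    ld:reagent-name "Chloroform" ;
    ld:causes-disease "central nervous system depression" .

ld:hazard-trizol
    ld:reagent-name "TRIzol" ;
    ld:causes-disease "chemical burn" .

ld:hazard-ethanol
    ld:reagent-name "Ethanol" ;
    ld:causes-disease "toxic effect of alcohol" .

ld:hazard-isopropyl
    ld:reagent-name "Isopropyl alcohol" ;
    ld:causes-disease "toxic encephalopathy" .
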