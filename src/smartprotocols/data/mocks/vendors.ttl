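# Synthetic mock linked-data graph: reagent -> vendor offers.
# Local stand-in with the same join shape as a PubChem-style vendor list.
@prefix ld: <https://w3id.org/smart-protocols/mock#> .

ld:offer-trizol-invitrogen
    ld:reagent-name "TRIzol" ;
    ld:vendor-name "Invitrogen" ;
    ld:website "https://vendors.example/invitrogen/trizol" .

ld:offer-chloroform-sigma
    ld:reagent-name "Chloroform" ;
    ld:vendor-name "Sigma-Aldrich" ;
    ld:website "https://vendors.example/sigma/chloroform" .

ld:offer-sodium-chloride-merck
    ld:reagent-name "Sodium chloride" ;
    ld:vendor-name "Merck" ;
    ld:website "https://vendors.example/merck/nacl" .

ld:offer-sodium-chloride-sigma
    ld:reagent-name "Sodium chloride" ;
    ld:vendor-name "Sigma-Aldrich" ;
    ld:website "https://vendors.example/sigma/nacl" .

ld:offer-ethanol-merck
    ld:reagent-name "Ethanol" ;
    ld:vendor-name "Merck" ;
    ld:website "https://vendors.example/merck/ethanol" .
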