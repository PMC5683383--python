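# Synthetic mock linked-data graph: taxon -> taxonomic order membership.
# Local stand-in with the same join shape as a DBpedia-style taxon lookup.
@prefix ld: <https://w3id.org/smart-protocols/mock#> .

ld:taxon-mus-musculus
    ld:scientific-name "Mus musculus" ;
    ld:order-name "Rodentia" ;
    ld:abstract "The house mouse, a small mammal of the order Rodentia." .

ld:taxon-rattus-norvegicus
    ld:scientific-name "Rattus norvegicus" ;
    ld:order-name "Rodentia" ;
    ld:abstract "The brown rat, a common rodent model organism." .

ld:taxon-arabidopsis-thaliana
    ld:scientific-name "Arabidopsis thaliana" ;
    ld:order-name "Brassicales" ;
    ld:abstract "Thale cress, a small flowering plant model organism." .

ld:taxon-oryza-sativa
    ld:scientific-name "Oryza sativa" ;
    ld:order-name "Poales" ;
    ld:abstract "Asian rice." .

ld:taxon-mangifera-indica
    ld:scientific-name "Mangifera indica" ;
    ld:order-name "Sapindales" ;
    ld:abstract "The mango tree." .
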