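# The BEL curation subset

`coagkg` parses the slice of the Biological Expression Language (BEL 2.x)
needed to curate heme effects on the blood coagulation system: flat
term–relation–term statements with experimental-context annotations.
Nested statements, protein modifications, fusions and translocations are
rejected with a diagnostic naming the line.

## Grammar (EBNF)

```
document    = { line } ;
line        = blank | comment | header | set | unset | statement ;
comment     = ( "#" | "//" ) , { any } ;
header      = 'SET DOCUMENT' , key , "=" , value
            | 'DEFINE NAMESPACE' , ident , 'AS' , value ;
set         = 'SET' , key , "=" , value ;
unset       = 'UNSET' , ( key | 'ALL' ) ;
statement   = term , relation , term ;

term        = func , "(" , inner , ")"
            | 'act' , "(" , term , ")" ;
func        = 'p' | 'g' | 'r' | 'm' | 'a' | 'bp' | 'path'
            | 'complex' | 'rxn' | long-form ;
inner       = namespace , ":" , name          (* leaf *)
            | term , { "," , term } ;         (* complex / rxn only *)
namespace   = 'HGNC' | 'CHEBI' | 'MESH' | 'GO' | 'TEXT' ;
name        = ident | quoted ;

relation    = "->" | "=>" | "-|" | "=|" | "--" | 'reg'
            | 'increases' | 'directlyIncreases' | 'decreases'
            | 'directlyDecreases' | 'association' | 'regulates' ;
```

Files are UTF-8 with extension `.bel`. Long-form function keywords
(`proteinAbundance`, `biologicalProcess`, ...) are accepted on input; the
serializer always emits the short forms and the relation symbols.
A `complex(...)` must list at least two component terms; named complexes
(`complex(GO:...)`) are outside the subset.

## Annotations

`SET key = "value"` opens an annotation that applies to every following
statement until `UNSET key` or `UNSET ALL`. Recognized keys:

| key       | value                                            |
|-----------|--------------------------------------------------|
| Citation  | PMID digits or `NA`                              |
| Evidence  | free text supporting the statement               |
| CellType  | free text (e.g. `endothelial cell`, `platelet`)  |
| Species   | NCBI taxon id                                    |
| Setting   | `in vitro` / `in vivo` / `ex vivo`               |
| Dose      | `[up to] <number> <µM\|mM\|nmol\|µmol/kg\|mg/kg>`|
| Route     | `incubation` / `intravenous` / `retroorbital`    |
| KD        | `<number> <nM\|µM>` equilibrium binding affinity |

Unknown keys are preserved verbatim (with a warning); dose or K_D strings
that do not match the pattern are kept as free text and flagged rather than
dropped.

## Entity normalization

After parsing, `normalize_document` applies the curation rules: the heme
synonyms *heme*, *hemin* and *hematin* (any namespace, any case) map to the
single canonical entity `a(CHEBI:heme)`, and statements naming therapeutic
heme formulations (*heme arginate*, *heme-albumin*) are excluded, since
those preparations were designed to avoid free-heme side effects. Both
tables ship as editable TSVs under `src/coagkg/data/`.

## Node identity

The canonical node key is `(function, namespace, case-folded name)` for leaf
terms and the function plus the sorted component keys for complexes and
reactions, so component order and name case never create duplicate nodes.
The `act(...)` modifier marks molecular activity on a statement but does not
create a separate node.
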