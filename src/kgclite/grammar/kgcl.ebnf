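(* Controlled natural language for ontology/KG change commands.

   One command per line. Leading keywords match case-insensitively; one
   trailing sentence period is tolerated. The reference implementation is
   a hand-written recursive-descent parser (kgclite.cnl) equivalent to
   this grammar.
*)

command        = rename | obsoletion | node_deletion | edge_deletion
               | class_creation | new_synonym | remove_synonym
               | replace_synonym | new_definition | remove_definition
               | change_definition | edge_creation | node_move
               | predicate_change ;

rename            = "rename" , node , "from" , quoted , "to" , quoted ;
obsoletion        = "obsolete" , node , [ "with" , "replacement" , node ] ;
node_deletion     = "delete" , "node" , node ;
edge_deletion     = "delete" , "edge" , node , pred , node ;
class_creation    = "create" , quoted ;
new_synonym       = "create" , [ scope ] , "synonym" , quoted , "for" , node
                  | "add" , [ scope ] , "synonym" , quoted , "to" , node ;
remove_synonym    = "remove" , "synonym" , quoted , "for" , node ;
replace_synonym   = "replace" , "synonym" , quoted , "with" , quoted ,
                    "for" , node ;
new_definition    = "add" , "definition" , quoted , "to" , node ;
remove_definition = "remove" , "definition" , "for" , node ;
change_definition = "change" , "definition" , "of" , node , "to" , quoted ;
edge_creation     = "create" , "edge" , node , pred , node ;
node_move         = "move" , node , "from" , node , "to" , node , [ via ]
                  | "move" , node , "under" , node , [ via ] ;
predicate_change  = "change" , "relationship" , "between" , node , "and" ,
                    node , "from" , pred , "to" , pred ;

(* "via <pred>" is a package extension: it lets a move over a predicate
   other than the default hierarchy predicate (is_a) round-trip. *)
via    = "via" , pred ;

scope  = "exact" | "narrow" | "broad" | "related" ;
node   = CURIE | quoted ;          (* quoted CURIE-shaped text = CURIE ref *)
pred   = CURIE | IDENTIFIER | quoted ;  (* bare aliases: is_a, part_of *)
quoted = "'" , text , "'" | '"' , text , '"'
       | "‘" , text , "’" | "“" , text , "”" ;
       (* inside quoted text, backslash escapes the closing quote char *)

CURIE      = PREFIX , ":" , LOCALPART ;
PREFIX     = letter , { letter | digit | "_" | "." | "-" } ;
LOCALPART  = { letter | digit | "_" | "." | "#" | "-" }- ;
IDENTIFIER = letter , { letter | digit | "_" } ;
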