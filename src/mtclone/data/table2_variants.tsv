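patient_id	variant	compartment
C1	m.11529T>C	BC
C2	m.1415G>A	BC
C2	m.4107C>T	BC
C2	m.1646T>C	CBC
C2	m.7937T>C	CBC
C3	m.6899G>A	BC
C5	m.1982G>A	BC+CBC
C8	m.14207G>A	BC+CBC
C9	m.3526G>A	CBC
C9	m.3833T>C	CBC
C9	m.16078A>G	BC+CBC
C10	m.2614T>C	CBC
C12	m.6642A>G	CBC
C13	m.9591G>A	BC+CBC
C14	m.10628C>T	CBC
C17	m.3213A>C	BC
C17	m.13151T>C	CBC
C18	m.2233T>C	CBC
C18	m.3117C>T	CBC
C19	m.1743T>C	CBC
C19	m.3849G>A	BC+CBC
C20	m.2470G>A	BC
C20	m.11723A>T	BC
C21	m.15853C>T	BC
C21	m.1776G>A	CBC
C22	m.3019G>A	BC
C22	m.9525G>A	BC
C22	m.12383T>C	CBC
C25	m.11642G>A	CBC
C27	m.5070A>G	CBC
C27	m.2492G>A	BC+CBC
C27	m.13633G>A	BC+CBC
C28	m.3153T>C	BC
C30	m.5212T>C	CBC
C30	m.1641G>A	BC+CBC
C30	m.3146G>A	BC+CBC
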