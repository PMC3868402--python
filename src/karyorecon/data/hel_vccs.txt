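# HEL cell line (VCCS specimen), near-triploid composite karyotype, ISCN 2013.
56∼62,<3n>,X,-X,-Y[11],der(1)t(1;15)(p36.3;q22.31)[11],der(2)t(2;10)(q22;q24)[10],der(?3;18)(q1?0;q10)[10],der(4)t(4;14)(p15.33;q23.3)del(4)(p15.32p15.32)[11],der(4;20)(4pter->4p10::20q10->20q11.1::20q13.33->20q13.33::11q23.2->11qter)[10],der(5;17)(p10;q10)[10],der(6)t(1;6)(p21.3;p22.3)[11],der(6)t(3;6)(p14.3;q21)[11],-7[11],+der(8)t(4;8)(q32.1;p12)[5],+der(8)(4qter->4q32.1::8p12->8q22.1::13q21.31->13qter)[6],-9[11],der(9)(18qter->18q22.1::11q22.1->11q13.1::20q13.33->20q13.33::20q11.21->20q11.23::20q11.23->20q11.22::20q11.22->20q11.23::20q11.23->20q11.21::19p13.?->19p13.?::22p11∼2->22p12∼3::9p24.3->9p21.3::9p21.3->9p21.2::9p21.1->9qter)[11],der(10)t(10;18)(p12;q11.2)t(2;10)(q22;q24)[11],der(10;19)(p10;q10)[11],+der(10;19)[9],-11[11],-14[11],-15[11],-16[11],-18[4],r(18)(::p11.23->q12::)[7],der(18)t(10;18)(p12.1;q11.2)[11],+der(19)(15qter->15q26.2::11q25->11q24.1::20q13.33->20q13.33::11q23.2->11q25::20q11.1->20q11.1::19q10->19q12::6q21->6qter)[11],+19[2],der(20)(15qter->15q11.2::20q10->20q11.1::20q13.33->20q13.33::11q23.2->11qter)[10],+r(20)(::20p11.1q11.21::19p13.?->19p13.?::)[10],dup(21)(q21.1qter)[10],psu dic(22;9)(p12∼3;p21.3)del(9)(p21.3p21.3)amp(9)(p24.3p21.2)amp(22)(p11p11∼3)[11],-22[11]
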