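<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="assayKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="open_area"/>
      <xs:enumeration value="covered_area"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="wellName">
    <xs:restriction base="xs:string">
      <xs:pattern value="[A-Z][1-9][0-9]*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="experiment">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="plate">
          <xs:complexType>
            <xs:attribute name="rows" type="xs:positiveInteger" use="required"/>
            <xs:attribute name="columns" type="xs:positiveInteger" use="required"/>
            <xs:attribute name="label" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="conditions">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="condition" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="metadata" minOccurs="0">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="entry" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:simpleContent>
                                <xs:extension base="xs:string">
                                  <xs:attribute name="key" type="xs:string" use="required"/>
                                </xs:extension>
                              </xs:simpleContent>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="wells">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="well" type="wellName" minOccurs="1" maxOccurs="unbounded"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="cell_line" type="xs:string"/>
                  <xs:attribute name="treatment" type="xs:string"/>
                  <xs:attribute name="dose" type="xs:double"/>
                  <xs:attribute name="dose_unit" type="xs:string"/>
                  <xs:attribute name="assay_kind" type="assayKind" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="data" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="series" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="point" minOccurs="2" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="time" type="xs:double" use="required"/>
                        <xs:attribute name="area" type="xs:double" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="well" type="wellName" use="required"/>
                  <xs:attribute name="source_label" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="schema_version" type="xs:string" use="required"/>
      <xs:attribute name="identifier" type="xs:string" use="required"/>
      <xs:attribute name="project" type="xs:string"/>
      <xs:attribute name="date" type="xs:string"/>
      <xs:attribute name="time_unit" type="xs:string"/>
      <xs:attribute name="area_unit" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
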